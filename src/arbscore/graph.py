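"""Core directed-graph container and structural predicates.

The package works on simple directed graphs over opaque string node labels.
:class:`DirectedGraph` is a thin immutable container; all heavy graph
algorithms are delegated to :mod:`networkx` behind this surface.

The predicates implement the nested family of structures that the
arborescence score is built on:

* *DAG* — no directed cycle (no strongly connected component of size >= 2
  and no self-loop).
* *directed tree* — a DAG whose undirected skeleton has no simple cycle
  (per weakly connected component, ``#edges == #nodes - 1``).
* *arborescence* — a weakly connected directed tree with exactly one node
  of in-degree 0 (the root) and every other node of in-degree 1; every
  edge points away from the root.
* *arborescence forest* — every weakly connected component is an
  arborescence.

Every arborescence is a directed tree, and every directed tree is a DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DirectedGraph",
    "SCCPartition",
    "find_sccs",
    "is_dag",
    "is_directed_tree",
    "is_arborescence",
    "is_arborescence_forest",
]


@dataclass(frozen=True)
class DirectedGraph:
    """A simple directed graph: a node set and a set of ordered edges.

    Node labels are opaque strings preserved verbatim; ``(i, j)`` and
    ``(j, i)`` are distinct edges. Duplicate edges collapse on
    construction (``edges`` is a set). Self-loops are allowed and
    queryable via :attr:`self_loops`.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint outside the node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "DirectedGraph":
        """Build a graph from an edge iterable plus optional isolated nodes."""
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        node_set = frozenset(str(n) for n in nodes) | frozenset(
            x for e in edge_set for x in e
        )
        return cls(node_set, edge_set)

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        return cls.from_edges(g.edges(), nodes=g.nodes())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def self_loops(self) -> frozenset[str]:
        """Nodes carrying a self-loop edge."""
        return frozenset(u for u, v in self.edges if u == v)

    def in_degree(self, node: str) -> int:
        return sum(1 for _, v in self.edges if v == node)

    def out_degree(self, node: str) -> int:
        return sum(1 for u, _ in self.edges if u == node)

    def degree_sequence(self) -> dict[str, tuple[int, int]]:
        """Per-node ``(in_degree, out_degree)`` map."""
        ind = {n: 0 for n in self.nodes}
        outd = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            outd[u] += 1
            ind[v] += 1
        return {n: (ind[n], outd[n]) for n in self.nodes}


@dataclass(frozen=True)
class SCCPartition:
    """Partition of a graph's nodes into maximal strongly connected components."""

    components: tuple[frozenset[str], ...]
    membership: Mapping[str, int] = field(hash=False)

    def component_of(self, node: str) -> frozenset[str]:
        return self.components[self.membership[node]]


def find_sccs(g: DirectedGraph) -> SCCPartition:
    """Maximal strongly connected components of ``g``.

    Singleton nodes (including nodes with self-loops) form their own
    components; an empty graph yields an empty partition. Components are
    returned in a deterministic order (sorted by smallest member label).
    Uses networkx's iterative linear-time SCC algorithm, so deep graphs
    cannot overflow the call stack.
    """
    comps = [frozenset(c) for c in nx.strongly_connected_components(g.to_networkx())]
    comps.sort(key=lambda c: min(c))
    membership = {n: i for i, c in enumerate(comps) for n in c}
    return SCCPartition(tuple(comps), membership)


def is_dag(g: DirectedGraph) -> bool:
    """True iff ``g`` has no directed cycle.

    Equivalent to: no SCC of size >= 2 and no self-loop.
    """
    if g.self_loops:
        return False
    return nx.is_directed_acyclic_graph(g.to_networkx())


def is_directed_tree(g: DirectedGraph) -> bool:
    """True iff ``g`` is a DAG whose undirected skeleton is a forest."""
    if not is_dag(g):
        return False
    skeleton = g.to_networkx().to_undirected(as_view=False)
    # a simple undirected graph is a forest iff every component has n-1 edges
    return all(
        skeleton.subgraph(c).number_of_edges() == len(c) - 1
        for c in nx.connected_components(skeleton)
    )


def is_arborescence(g: DirectedGraph) -> bool:
    """True iff ``g`` is a weakly connected directed tree with a unique root.

    All nodes must have in-degree 1 except exactly one root of in-degree 0;
    equivalently every edge points away from the single root.
    """
    if g.n_nodes == 0:
        return False
    if not is_directed_tree(g):
        return False
    if not nx.is_weakly_connected(g.to_networkx()):
        return False
    indeg = [g.in_degree(n) for n in g.nodes]
    return indeg.count(0) == 1 and all(d <= 1 for d in indeg)


def is_arborescence_forest(g: DirectedGraph) -> bool:
    """True iff every weakly connected component of ``g`` is an arborescence.

    The empty graph is vacuously a forest.
    """
    ng = g.to_networkx()
    for comp in nx.weakly_connected_components(ng):
        sub = DirectedGraph.from_edges(ng.subgraph(comp).edges(), nodes=comp)
        if not is_arborescence(sub):
            return False
    return True
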