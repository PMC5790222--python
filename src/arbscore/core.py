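"""The arborescence score: condensation, rooting, and the score itself.

A directed network is reduced to its arborescence forest in three steps:

1. **Condensation** — every strongly connected component (SCC) is collapsed
   into a single "super node"; inter-component edges are inherited by the
   super nodes (parallel edges merge, intra-component edges and self-loops
   are dropped). The result is always a DAG.

2. **Rooting** — every node of the condensed DAG with in-degree > 1 keeps
   only the incoming edge whose source has the *lowest* out-closeness
   centrality. Nodes near a root reach more nodes through longer paths, so
   their closeness is low; keeping the lowest-closeness parent keeps the
   edge that comes "from above". After this step the graph is an
   arborescence forest.

3. **Score** — ``A_G = |E*| / |E|``: the fraction of the original edges
   that survive into the forest. ``A_G = 1`` iff the input was already an
   arborescence forest; ``A_G = 0`` iff the whole graph was a single SCC.

The surviving edge count never depends on which parent wins a closeness
tie: a forest on ``|V*|`` component nodes with ``z`` roots always has
``|V*| - z`` edges, and the roots are exactly the in-degree-0 nodes of the
condensed DAG. Ties are broken by the lexicographically smallest component
identifier so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import networkx as nx

from .graph import (
    DirectedGraph,
    SCCPartition,
    find_sccs,
    is_arborescence_forest,
    is_dag,
)

__all__ = [
    "CondensedDAG",
    "ArborescenceResult",
    "condense",
    "out_closeness",
    "root_forest",
    "arborescence_score",
    "component_identifier",
]

#: prefix used for identifiers of multi-node strongly connected components
SCC_PREFIX = "scc:"


def component_identifier(component: frozenset[str]) -> str:
    """Human-readable identifier for an SCC.

    Singletons keep their own label; components with >= 2 members are
    named after their lexicographically smallest member, prefixed with
    ``scc:`` so condensed output stays readable.
    """
    smallest = min(component)
    return smallest if len(component) == 1 else SCC_PREFIX + smallest


@dataclass(frozen=True)
class CondensedDAG:
    """A graph's SCC partition together with the component-level DAG."""

    partition: SCCPartition
    dag: DirectedGraph
    component_label: Mapping[int, str]

    def members(self, identifier: str) -> frozenset[str]:
        """Original nodes collapsed into the component ``identifier``."""
        for idx, label in self.component_label.items():
            if label == identifier:
                return self.partition.components[idx]
        raise KeyError(identifier)


@dataclass(frozen=True)
class ArborescenceResult:
    """Full output of the arborescence reduction of one input graph.

    ``score == n_forest_edges / n_edges`` and, in closed form,
    ``n_forest_edges == n_condensed_nodes - len(roots)``.
    ``n_condensed_edges`` is the edge count of the condensed DAG *before*
    rooting (the size of the cycle-free reduced graph); ``n_forest_edges``
    is the count after rooting, the numerator of the score.
    """

    n_nodes: int
    n_edges: int
    n_condensed_nodes: int
    n_condensed_edges: int
    forest: DirectedGraph
    n_forest_edges: int
    roots: tuple[str, ...]
    score: float
    score_fraction: Fraction
    removed_in_condensation: tuple[tuple[str, str], ...]
    removed_in_rooting: tuple[tuple[str, str], ...]
    condensed: CondensedDAG


def condense(g: DirectedGraph) -> CondensedDAG:
    """Collapse every SCC of ``g`` into a single node.

    The condensed graph has one node per SCC and an edge ``(P, Q)`` iff
    some original edge runs from a node of ``P`` to a node of ``Q`` with
    ``P != Q``. Parallel inter-component edges merge; self-loops and
    intra-component edges vanish. The result is acyclic.
    """
    partition = find_sccs(g)
    labels = {i: component_identifier(c) for i, c in enumerate(partition.components)}
    dag_edges = {
        (labels[partition.membership[u]], labels[partition.membership[v]])
        for u, v in g.edges
        if partition.membership[u] != partition.membership[v]
    }
    dag = DirectedGraph.from_edges(dag_edges, nodes=labels.values())
    return CondensedDAG(partition, dag, labels)


def out_closeness(d: DirectedGraph) -> dict[str, float]:
    """Out-closeness centrality ``C_i`` of every node of ``d``.

    ``C_i = 1 / sum_j d(i, j)`` where the sum runs over the nodes *j*
    reachable from *i* and ``d(i, j)`` counts hops on shortest directed
    paths. Leaves (no outgoing edge, hence nothing reachable) get
    ``C_i = 0``.
    """
    ng = d.to_networkx()
    values: dict[str, float] = {}
    for node in d.nodes:
        dist = nx.single_source_shortest_path_length(ng, node)
        total = sum(length for target, length in dist.items() if target != node)
        values[node] = 1.0 / total if total > 0 else 0.0
    return values


def root_forest(
    cd: CondensedDAG,
) -> tuple[DirectedGraph, tuple[str, ...], tuple[tuple[str, str], ...]]:
    """Prune the condensed DAG down to an arborescence forest.

    For every node of in-degree > 1, all incoming edges are removed except
    the one whose source has minimal out-closeness (ties broken toward the
    lexicographically smallest source identifier). Returns the forest, its
    roots (in-degree-0 nodes, sorted), and the removed edges.

    Raises :class:`ValueError` on cyclic input: condensation must run first.
    """
    if not is_dag(cd.dag):
        raise ValueError("root_forest requires an acyclic graph; run condense() first")
    closeness = out_closeness(cd.dag)
    predecessors: dict[str, list[str]] = {n: [] for n in cd.dag.nodes}
    for u, v in cd.dag.edges:
        predecessors[v].append(u)
    kept: set[tuple[str, str]] = set()
    removed: list[tuple[str, str]] = []
    for v, preds in predecessors.items():
        if not preds:
            continue
        winner = min(preds, key=lambda u: (closeness[u], u))
        kept.add((winner, v))
        removed.extend((u, v) for u in preds if u != winner)
    forest = DirectedGraph.from_edges(kept, nodes=cd.dag.nodes)
    roots = tuple(sorted(n for n in forest.nodes if forest.in_degree(n) == 0))
    return forest, roots, tuple(sorted(removed))


def arborescence_score(g: DirectedGraph) -> ArborescenceResult:
    """Run the full condensation → rooting → scoring pipeline on ``g``.

    Raises :class:`ValueError` if ``g`` has no edges (the score's
    denominator would vanish).
    """
    if g.n_edges == 0:
        raise ValueError("arborescence score undefined for empty edge set")
    cd = condense(g)
    forest, roots, removed_rooting = root_forest(cd)
    assert is_arborescence_forest(forest)
    membership = cd.partition.membership
    removed_condensation = tuple(
        sorted(
            (u, v)
            for u, v in g.edges
            if membership[u] == membership[v]
        )
    )
    n_forest_edges = forest.n_edges
    fraction = Fraction(n_forest_edges, g.n_edges)
    return ArborescenceResult(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        n_condensed_nodes=cd.dag.n_nodes,
        n_condensed_edges=cd.dag.n_edges,
        forest=forest,
        n_forest_edges=n_forest_edges,
        roots=roots,
        score=float(fraction),
        score_fraction=fraction,
        removed_in_condensation=removed_condensation,
        removed_in_rooting=removed_rooting,
        condensed=cd,
    )
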