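"""Comparison hierarchy measures: flow hierarchy, reaching centrality, agony.

These are the established alternatives the arborescence score is compared
against. All return values in [0, 1], higher meaning more hierarchical.

* **Flow hierarchy (FH)** — the fraction of edges not participating in any
  directed cycle. An edge lies on a cycle iff both endpoints sit in the
  same strongly connected component; self-loops always count as in-cycle.
* **Global reaching centrality (GRC)** — how much the best "reacher"
  dominates the rest: the mean gap between the maximum local reaching
  centrality and every node's own value. Equals 1 only for a star.
* **Agony** — ``1 - |E_a|/|E|`` where ``E_a`` is the set of backward edges
  under a node ranking chosen to minimise them. Only the DAG case (where a
  topological ranking gives a perfect score) and the score-for-a-given-
  ranking case are implemented; exact agony minimisation on cyclic graphs
  requires a dedicated solver and is deliberately out of scope.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx

from .graph import DirectedGraph, find_sccs, is_dag

__all__ = [
    "flow_hierarchy",
    "local_reaching_centrality",
    "global_reaching_centrality",
    "agony_score_from_ranking",
    "agony_score",
]


def flow_hierarchy(g: DirectedGraph) -> float:
    """Fraction of edges of ``g`` whose endpoints lie in different SCCs."""
    if g.n_edges == 0:
        raise ValueError("flow hierarchy undefined for empty edge set")
    membership = find_sccs(g).membership
    acyclic = sum(1 for u, v in g.edges if membership[u] != membership[v])
    return acyclic / g.n_edges


def local_reaching_centrality(g: DirectedGraph, node: str) -> float:
    """Fraction of the other ``|V| - 1`` nodes reachable from ``node``."""
    if node not in g.nodes:
        raise KeyError(f"node {node!r} not in graph")
    if g.n_nodes < 2:
        raise ValueError("reaching centrality undefined for a single-node graph")
    reachable = nx.descendants(g.to_networkx(), node)
    reachable.discard(node)
    return len(reachable) / (g.n_nodes - 1)


def global_reaching_centrality(g: DirectedGraph) -> float:
    """GRC = mean over nodes of (max local reaching centrality − own value).

    Uses plain reachable fractions (unweighted, hop-count-free): the
    measure asks *whether* a node can command another, not how far away
    it sits.
    """
    if g.n_nodes < 2:
        raise ValueError("GRC undefined for a single-node graph")
    ng = g.to_networkx()
    n = g.n_nodes
    local = {
        node: len(nx.descendants(ng, node) - {node}) / (n - 1) for node in g.nodes
    }
    c_max = max(local.values())
    return sum(c_max - c for c in local.values()) / (n - 1)


def agony_score_from_ranking(g: DirectedGraph, ranks: Mapping[str, int]) -> float:
    """Agony-style hierarchy score of ``g`` under a supplied ranking.

    ``ranks`` maps every node to an integer level, 0 at the top. An edge
    ``(u, v)`` is *backward* iff ``ranks[u] >= ranks[v]``: edges are
    expected to flow strictly downward, so a flat edge between peers
    counts against the hierarchy (otherwise the all-equal ranking would
    trivially be perfect). Returns ``1 - backward/|E|``.
    """
    if g.n_edges == 0:
        raise ValueError("agony score undefined for empty edge set")
    missing = {u for e in g.edges for u in e} - set(ranks)
    if missing:
        raise KeyError(f"ranking missing nodes: {sorted(missing)[:5]}")
    backward = sum(1 for u, v in g.edges if ranks[u] >= ranks[v])
    return 1.0 - backward / g.n_edges


def agony_score(g: DirectedGraph) -> float:
    """Optimal agony score for a DAG (always 1).

    A DAG admits a topological ranking with zero backward edges, so its
    minimum-agony score is exactly 1; the function assigns topological
    ranks and evaluates them to keep the code path honest. Cyclic inputs
    raise: supply a ranking to :func:`agony_score_from_ranking` instead.
    """
    if g.n_edges == 0:
        raise ValueError("agony score undefined for empty edge set")
    if not is_dag(g):
        raise ValueError(
            "exact agony minimisation is not implemented for cyclic graphs; "
            "supply a ranking via agony_score_from_ranking"
        )
    order = list(nx.topological_sort(g.to_networkx()))
    ranks = {node: i for i, node in enumerate(order)}
    return agony_score_from_ranking(g, ranks)
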