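"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own graph algorithms:
reachability is computed by boolean matrix closure (Floyd–Warshall style)
so that SCC detection, flow hierarchy and friends can be checked against
a second, independent route on small graphs.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from arbscore.graph import DirectedGraph


def random_graph(rng: random.Random, n_max: int = 8, p: float = 0.25) -> DirectedGraph:
    """Small random digraph (self-loops allowed) for corpus-style tests."""
    n = rng.randint(1, n_max)
    labels = [str(i) for i in range(n)]
    edges = [
        (u, v)
        for u in labels
        for v in labels
        if rng.random() < p and (u != v or rng.random() < 0.3)
    ]
    return DirectedGraph.from_edges(edges, nodes=labels)


def graph_corpus(seed: int, size: int, n_max: int = 8, p: float = 0.25):
    rng = random.Random(seed)
    return [random_graph(rng, n_max=n_max, p=p) for _ in range(size)]


def reachability_matrix(g: DirectedGraph) -> tuple[list[str], np.ndarray]:
    """Transitive closure by repeated boolean squaring; independent oracle."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges:
        adj[idx[u], idx[v]] = True
    reach = adj.copy()
    for _ in range(max(1, n.bit_length())):
        reach = reach | (reach @ reach)
    return nodes, reach


def brute_force_sccs(g: DirectedGraph) -> set[frozenset[str]]:
    """Mutual-reachability classes from the transitive closure."""
    nodes, reach = reachability_matrix(g)
    mutual = reach & reach.T
    comps: list[set[str]] = []
    assigned: set[str] = set()
    for i, u in enumerate(nodes):
        if u in assigned:
            continue
        comp = {u} | {nodes[j] for j in range(len(nodes)) if mutual[i, j] and mutual[j, i]}
        comps.append(comp)
        assigned |= comp
    return {frozenset(c) for c in comps}


def brute_force_flow_hierarchy(g: DirectedGraph) -> float:
    """Per-edge cycle membership by exhaustive simple-path search."""

    def on_cycle(u: str, v: str) -> bool:
        # edge (u, v) lies on a cycle iff some path leads back from v to u
        if u == v:
            return True
        frontier, seen = [v], {v}
        while frontier:
            x = frontier.pop()
            for a, b in g.edges:
                if a == x and b not in seen:
                    if b == u:
                        return True
                    seen.add(b)
                    frontier.append(b)
        return False

    in_cycle = sum(1 for u, v in g.edges if on_cycle(u, v))
    return 1 - in_cycle / g.n_edges


def enumerate_paths(g: DirectedGraph, src: str, dst: str) -> list[tuple[str, ...]]:
    """All simple directed paths src → dst, by exhaustive enumeration."""
    paths = []

    def walk(node: str, trail: tuple[str, ...]):
        if node == dst:
            paths.append(trail)
            return
        for u, v in g.edges:
            if u == node and v not in trail:
                walk(v, trail + (v,))

    walk(src, (src,))
    return paths


@pytest.fixture
def small_corpus():
    return graph_corpus(seed=20260930, size=120)
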