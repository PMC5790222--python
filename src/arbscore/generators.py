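"""Synthetic graph generators, toy fixtures, and the random-model sweeps.

Three random families probe the hierarchy measures:

* **Directed Erdős–Rényi** (``er``) — a fixed number of edges placed
  uniformly at random; no hierarchy by construction.
* **Direction-randomised Watts–Strogatz** (``ws``) — a small-world ring
  lattice with rewiring probability *p*, each undirected edge then given a
  uniformly random direction; structured but still non-hierarchical.
* **Old→new preferential attachment** (``pa``) — Barabási–Albert growth
  with every edge oriented from the older (lower creation index) node to
  the newcomer. The result is a DAG in which every non-seed node has
  in-degree *m*; rooting must drop ``m - 1`` parents per node, so the
  arborescence score is ~``1/m`` while flow hierarchy and agony are
  exactly 1.

The toy fixtures (a small DAG, a two-rooted directed tree, an
arborescence, and a 15-node worked example with two non-trivial SCCs)
reproduce the structures used to illustrate the score; each fixture
self-checks its structural facts before being served.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .baselines import flow_hierarchy, global_reaching_centrality
from .core import arborescence_score
from .graph import (
    DirectedGraph,
    find_sccs,
    is_arborescence,
    is_dag,
    is_directed_tree,
)

__all__ = [
    "SweepRecord",
    "gen_erdos_renyi",
    "gen_watts_strogatz_directed",
    "gen_preferential_attachment_directed",
    "gen_balanced_arborescence",
    "gen_wheel_flipped",
    "gen_star",
    "gen_cycle",
    "gen_multiroot_toy",
    "fixture_dag_example",
    "fixture_tree_example",
    "fixture_arborescence_example",
    "fixture_worked_example",
    "sweep",
    "pa_er_ratio",
    "GENERATORS",
    "SWEEP_MEASURES",
]


def gen_erdos_renyi(n: int, m_edges: int, rng_seed: int = 0) -> DirectedGraph:
    """Directed G(n, m): exactly ``m_edges`` distinct non-self-loop edges."""
    if not 0 <= m_edges <= n * (n - 1):
        raise ValueError(f"m_edges must be in [0, n(n-1)] = [0, {n * (n - 1)}]")
    g = nx.gnm_random_graph(n, m_edges, seed=rng_seed, directed=True)
    return DirectedGraph.from_edges(g.edges(), nodes=g.nodes())


def gen_watts_strogatz_directed(
    n: int, k: int, p: float = 0.05, rng_seed: int = 0
) -> DirectedGraph:
    """Watts–Strogatz ring lattice, rewired, then randomly oriented.

    Each node starts linked to its ``k`` nearest ring neighbours
    (``k`` even, ``k < n``); each undirected edge is rewired with
    probability ``p`` and finally given a uniformly random direction, so
    the edge count is exactly ``n * k / 2``.
    """
    if k % 2 != 0 or not 0 < k < n:
        raise ValueError("k must be even and 0 < k < n")
    rng = random.Random(rng_seed)
    und = nx.watts_strogatz_graph(n, k, p, seed=rng.randrange(2**31))
    edges = [(u, v) if rng.random() < 0.5 else (v, u) for u, v in und.edges()]
    return DirectedGraph.from_edges(edges, nodes=und.nodes())


def gen_preferential_attachment_directed(
    n: int, m: int, rng_seed: int = 0
) -> DirectedGraph:
    """Barabási–Albert growth with edges oriented old → new.

    Starts from ``m`` isolated seed nodes; each newcomer attaches to ``m``
    distinct existing nodes with probability proportional to degree (the
    first newcomer therefore attaches to all seeds). Orienting every edge
    from the lower to the higher creation index yields a DAG in which
    every non-seed node has in-degree exactly ``m``.
    """
    if not 1 <= m < n:
        raise ValueError("m must satisfy 1 <= m < n")
    rng = random.Random(rng_seed)
    edges: list[tuple[int, int]] = []
    # one entry per half-edge: sampling from this list is sampling by degree
    repeated: list[int] = []
    for new in range(m, n):
        if new == m:
            # all existing nodes still have degree zero: attach to every seed
            targets: set[int] = set(range(m))
        else:
            targets = set()
            while len(targets) < m:
                targets.add(rng.choice(repeated))
        for old in sorted(targets):
            edges.append((old, new))
            repeated.append(old)
            repeated.append(new)
    return DirectedGraph.from_edges(edges, nodes=range(n))


def gen_balanced_arborescence(branching: int, height: int) -> DirectedGraph:
    """Complete out-tree: every internal node has ``branching`` children."""
    if branching < 1 or height < 0:
        raise ValueError("need branching >= 1 and height >= 0")
    g = nx.balanced_tree(branching, height, create_using=nx.DiGraph)
    return DirectedGraph.from_edges(g.edges(), nodes=g.nodes())


def gen_wheel_flipped(n_rim: int) -> DirectedGraph:
    """Hub pointing at a directed rim cycle with one edge reversed.

    The hub links to every rim node and the rim forms a one-directional
    circle except for a single flipped edge, which breaks the only
    directed cycle: the graph is a DAG with ``2 * n_rim`` edges, yet full
    of horizontal rim connections.
    """
    if n_rim < 3:
        raise ValueError("need at least 3 rim nodes")
    edges = [("hub", f"r{i}") for i in range(n_rim)]
    edges += [(f"r{i}", f"r{(i + 1) % n_rim}") for i in range(n_rim - 1)]
    # the closing edge runs against the circle's direction
    edges.append(("r0", f"r{n_rim - 1}"))
    return DirectedGraph.from_edges(edges)


def gen_star(n: int) -> DirectedGraph:
    """Hub with out-edges to ``n - 1`` spokes and no other edges."""
    if n < 2:
        raise ValueError("star needs n >= 2")
    return DirectedGraph.from_edges(("hub", f"s{i}") for i in range(n - 1))


def gen_cycle(n: int) -> DirectedGraph:
    """Single directed cycle on ``n`` nodes."""
    if n < 2:
        raise ValueError("cycle needs n >= 2")
    return DirectedGraph.from_edges((str(i), str((i + 1) % n)) for i in range(n))


def gen_multiroot_toy() -> DirectedGraph:
    """Small DAG with two roots feeding shared descendants."""
    g = DirectedGraph.from_edges(
        [("a", "c"), ("b", "c"), ("a", "d"), ("b", "e"), ("c", "f"), ("c", "g")]
    )
    assert is_dag(g)
    assert sum(1 for v in g.nodes if g.in_degree(v) == 0) >= 2
    return g


def _checked(g: DirectedGraph, *facts: bool) -> DirectedGraph:
    if not all(facts):
        raise AssertionError("fixture failed its structural self-test")
    return g


def fixture_dag_example() -> DirectedGraph:
    """A 9-node, 10-edge DAG that is not a directed tree.

    Nodes 5 and 6 have in-degree 2, and the undirected skeleton contains
    the cycle 0–2–5–1–0, so two edges must go in the rooting step:
    the arborescence score is 8/10 = 0.8.
    """
    g = DirectedGraph.from_edges(
        [
            ("0", "1"), ("0", "2"), ("0", "3"),
            ("1", "5"), ("2", "5"),
            ("2", "6"), ("3", "6"),
            ("3", "4"), ("5", "7"), ("6", "8"),
        ]
    )
    return _checked(
        g,
        g.n_edges == 10,
        is_dag(g),
        not is_directed_tree(g),
        g.in_degree("5") == 2,
        g.in_degree("6") == 2,
    )


def fixture_tree_example() -> DirectedGraph:
    """A 9-node, 8-edge directed tree with two in-degree-0 nodes (0 and 3).

    Not an arborescence: node 2 has two parents and no unique root exists.
    Rooting deletes the (3, 2) edge — node 0 sits above a deeper subtree,
    hence has the lower out-closeness — leaving two arborescences rooted
    at 0 and 3 and a score of 7/8 = 0.875.
    """
    g = DirectedGraph.from_edges(
        [
            ("0", "1"), ("0", "2"),
            ("1", "4"), ("4", "7"),
            ("2", "5"), ("2", "6"),
            ("3", "2"), ("3", "8"),
        ]
    )
    return _checked(
        g,
        g.n_edges == 8,
        is_directed_tree(g),
        not is_arborescence(g),
        {v for v in g.nodes if g.in_degree(v) == 0} == {"0", "3"},
        ("3", "2") in g.edges,
    )


def fixture_arborescence_example() -> DirectedGraph:
    """A 7-node arborescence rooted at 0 (score 1 by construction)."""
    g = DirectedGraph.from_edges(
        [("0", "1"), ("0", "2"), ("1", "3"), ("1", "4"), ("2", "5"), ("2", "6")]
    )
    return _checked(g, is_arborescence(g), g.in_degree("0") == 0)


def fixture_worked_example() -> DirectedGraph:
    """The 15-node, 20-edge worked example with two non-trivial SCCs.

    Strongly connected components {6, 7, 8} and {11, 12, 13, 14} collapse
    into two super nodes, leaving a 10-node condensed DAG with a single
    source; 9 of the 20 original edges survive into the forest, so the
    arborescence score is 9/20 = 0.45.
    """
    g = DirectedGraph.from_edges(
        [
            # two strongly connected "teams"
            ("6", "7"), ("7", "8"), ("8", "6"),
            ("11", "12"), ("12", "13"), ("13", "14"), ("14", "11"),
            # the hierarchy threading through them
            ("0", "1"), ("0", "2"),
            ("1", "6"), ("2", "8"), ("2", "4"),
            ("7", "3"), ("8", "4"),
            ("3", "11"), ("4", "14"),
            ("12", "5"), ("13", "9"),
            ("5", "10"), ("9", "10"),
        ]
    )
    sccs = {c for c in find_sccs(g).components if len(c) > 1}
    return _checked(
        g,
        g.n_nodes == 15,
        g.n_edges == 20,
        sccs == {frozenset({"6", "7", "8"}), frozenset({"11", "12", "13", "14"})},
    )


GENERATORS = {
    "er": gen_erdos_renyi,
    "ws": gen_watts_strogatz_directed,
    "pa": gen_preferential_attachment_directed,
}

#: measures available to :func:`sweep`; agony is exact only on DAGs, so it
#: is meaningful for the ``pa`` model only
SWEEP_MEASURES = ("arb", "fh", "grc", "agony")


@dataclass(frozen=True)
class SweepRecord:
    """Mean ± sd of one measure over replicates of one generator setting."""

    model: str
    n_nodes: int
    n_edges: int
    measure: str
    mean: float
    sd: float
    n_replicates: int


def _sweep_graph(model: str, n: int, m_edges: int, seed: int) -> DirectedGraph:
    if model == "er":
        return gen_erdos_renyi(n, m_edges, rng_seed=seed)
    if model == "ws":
        k = max(2, round(2 * m_edges / n / 2) * 2)
        return gen_watts_strogatz_directed(n, k, rng_seed=seed)
    if model == "pa":
        # pick m so that m * (n - m) is as close as possible to m_edges
        m = min(range(1, n), key=lambda m: abs(m * (n - m) - m_edges))
        return gen_preferential_attachment_directed(n, m, rng_seed=seed)
    raise ValueError(f"unknown model {model!r}; choose from {sorted(GENERATORS)}")


def _measure_value(measure: str, g: DirectedGraph) -> float:
    from .baselines import agony_score

    if measure == "arb":
        return arborescence_score(g).score
    if measure == "fh":
        return flow_hierarchy(g)
    if measure == "grc":
        return global_reaching_centrality(g)
    if measure == "agony":
        return agony_score(g)
    raise ValueError(f"unknown measure {measure!r}")


def sweep(
    model: str,
    n: int = 100,
    edge_grid: Sequence[int] = (200, 300, 500, 800, 1200),
    n_replicates: int = 100,
    measures: Iterable[str] = ("arb", "fh", "grc"),
    rng_seed: int = 0,
) -> list[SweepRecord]:
    """Mean ± sd of each measure across seeded replicates per edge count.

    For the ``ws`` and ``pa`` models each grid value is mapped to the
    nearest feasible parameter (even ``k``, integer ``m``), so realised
    edge counts can differ slightly from the requested ones; the record
    reports the realised count.
    """
    import numpy as np

    records = []
    measures = list(measures)
    for grid_idx, m_edges in enumerate(edge_grid):
        values: dict[str, list[float]] = {meas: [] for meas in measures}
        realised = 0
        for rep in range(n_replicates):
            # distinct deterministic seed per (grid point, replicate)
            seed = (rng_seed * 1_000_003 + grid_idx * 10_007 + rep) % 2**31
            g = _sweep_graph(model, n, m_edges, seed=seed)
            realised = g.n_edges
            for meas in measures:
                values[meas].append(_measure_value(meas, g))
        for meas in measures:
            arr = np.asarray(values[meas])
            records.append(
                SweepRecord(
                    model=model,
                    n_nodes=n,
                    n_edges=realised,
                    measure=meas,
                    mean=float(arr.mean()),
                    sd=float(arr.std()),
                    n_replicates=n_replicates,
                )
            )
    return records


def pa_er_ratio(
    n: int = 100,
    edge_grid: Sequence[int] = (200, 300, 500, 800),
    n_replicates: int = 100,
    measures: Iterable[str] = ("arb", "fh", "grc"),
    rng_seed: int = 0,
) -> list[dict]:
    """Ratio of preferential-attachment to Erdős–Rényi mean scores.

    A large ``H_PA / H_ER`` means the measure separates a hub-rooted
    hierarchy from a matched random graph. When ``H_ER`` is zero the
    ratio is reported as ``inf`` (or ``nan`` if ``H_PA`` is zero too).
    """
    measures = list(measures)
    pa = sweep("pa", n, edge_grid, n_replicates, measures, rng_seed)
    er = sweep("er", n, edge_grid, n_replicates, measures, rng_seed)
    # sweep emits records grid-point by grid-point, so for a fixed measure
    # the k-th record of each model corresponds to edge_grid[k]
    pa_by = {meas: [r for r in pa if r.measure == meas] for meas in measures}
    er_by = {meas: [r for r in er if r.measure == meas] for meas in measures}
    rows = []
    for i, requested in enumerate(edge_grid):
        for meas in measures:
            h_pa = pa_by[meas][i].mean
            h_er = er_by[meas][i].mean
            if h_er > 0:
                ratio = h_pa / h_er
            else:
                ratio = float("inf") if h_pa > 0 else float("nan")
            rows.append(
                {
                    "requested_edges": requested,
                    "measure": meas,
                    "h_pa": h_pa,
                    "h_er": h_er,
                    "ratio": ratio,
                }
            )
    return rows
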