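# Methods

## Model and assumptions

`arbscore` treats hierarchy as a structural, edit-distance-like property
of a directed graph: the score is the largest fraction of edges that can
survive a reduction to an arborescence forest. The reduction is

1. **Condensation.** Strongly connected components (SCCs) are detected
   with networkx's iterative linear-time algorithm and collapsed into
   super nodes. A super node inherits the inbound and outbound edges of
   its members; parallel inter-component edges merge (the condensed DAG
   is simple), and intra-component edges — including self-loops — are
   dropped. Mutual reachability is taken as the definition of "no
   hierarchy": a team whose members all reach one another has no
   internal top-down order, so none of its internal edges can be part of
   one.
2. **Rooting.** On the condensed DAG, out-closeness
   `C_i = 1 / sum_j d(i, j)` is computed per node by BFS, the sum running
   over the nodes reachable from `i` (leaves get `C_i = 0`; unreachable
   nodes are simply excluded rather than contributing infinite terms).
   Each node of in-degree > 1 keeps only the incoming edge whose source
   has minimal closeness. The heuristic's premise: sources near the top
   of a hierarchy reach many nodes through long downward paths, which
   makes their closeness small, so the minimal-closeness parent is the
   one "above" the node. Closeness is computed on the condensed DAG,
   not the input graph, because the rooting step's job is to finish the
   already-condensed structure.
3. **Score.** `A_G = |E*| / |E|`, with `|E|` counting the distinct edges
   of the input (self-loops included — they can never survive, so they
   legitimately depress the score) and `|E*|` the forest edges.

Two bookkeeping quantities are deliberately kept distinct:
`n_condensed_edges`, the edge count of the condensed DAG after step 1
(the natural "size of the cycle-free reduced graph" to report for a real
network), and `n_forest_edges`, the post-rooting count that enters the
score. They coincide only when no node of the condensed DAG has two
parents.

### Determinism and tie-breaking

`|E*| = |V*| - z` with `z` the number of sources of the condensed DAG, so
the *score* is independent of every choice made during rooting; only the
forest's shape can vary. When several parents share the minimal
closeness, the edge from the lexicographically smallest component
identifier is kept, making the exported forest reproducible. Component
identifiers are the smallest member label, prefixed `scc:` for
multi-member components. Scores are carried as exact
`fractions.Fraction` values alongside floats, so equality tests never
depend on floating-point rounding.

Degenerate inputs: a graph with no edges has no score (error — the
denominator would vanish); isolated nodes are allowed and become
single-node roots, changing neither numerator nor denominator; rooting
called directly on a cyclic graph raises rather than looping.

## Baselines

* **Flow hierarchy** — fraction of edges whose endpoints lie in
  different SCCs; a self-loop counts as in-cycle. Equals 1 exactly on
  DAGs.
* **Reaching centrality** — the local value is the plain fraction of
  other nodes reachable from a node (no path-length weighting: the
  question is whether a node can command another, not from how far);
  GRC averages the gap to the maximum. GRC is 1 only for a star, which
  is why even perfect balanced trees score below 1 on it.
* **Agony** — `1 - backward_edges/|E|` under a node ranking. An edge is
  backward iff `rank(source) >= rank(target)`: ranks grow downward from
  0, and flat edges count as backward because otherwise the all-equal
  ranking would make every graph perfect. Exact agony minimisation on
  cyclic graphs needs a dedicated combinatorial solver and is out of
  scope here: `agony_score` handles the DAG case (topological ranks, a
  provably perfect score of 1, still computed rather than asserted) and
  raises on cyclic input; `agony_score_from_ranking` scores any graph
  under a caller-supplied ranking, and the CLI reports `n/a` for agony
  of cyclic files unless `--ranking` is given. The equal-ranks
  convention is isolated in `agony_score_from_ranking` so it could be
  flipped in one place.

## Null model

Significance uses the double edge switch: edges `a→b`, `c→d` become
`c→b`, `a→d`. A proposal aborts when a replacement edge already exists,
would be a self-loop, or the two draws coincide; aborts are retried and
do not count toward the swap budget, which defaults to `|E|` successful
switches. Per-node in- and out-degrees and the edge count are preserved
exactly. Each of the `n_models` replicas (default 1000) restarts from
the original graph with an independent RNG substream spawned from
`(seed, replicate_index)`, so results are bit-reproducible and
independent of evaluation order. Labels: `+` iff
`observed >= mean + 2*sd`, `-` iff `observed <= mean - 2*sd`, else `x`;
the null sd uses the population convention (ddof = 0). The pseudo
p-value is the plain fraction of replicas scoring `>=` the observation
(ties count as outscoring, no +1 smoothing).

Graphs whose degree sequence admits essentially no rewiring (a directed
star: every proposal recreates an existing hub edge) stall the switcher.
`double_edge_switch` raises by default after `100 × n_swaps` consecutive
aborts; `null_test` instead accepts the current — still
degree-preserving — state as the replica, so a star yields a null
distribution degenerate at the observed score, label `x`, pseudo p = 1,
which is the honest answer for a one-point ensemble. When the null sd is
0, `z` is reported as the sign limit (0 or ±inf) and the label falls
back to direct comparison with the mean.

## Synthetic generators

The generators double as the experimental conditions for validating the
measures:

* **Directed Erdős–Rényi** (`er`): exactly `m` distinct non-self-loop
  directed edges, uniformly at random — the no-hierarchy control.
* **Direction-randomised Watts–Strogatz** (`ws`): undirected ring
  lattice (`k` neighbours), rewired with probability `p = 0.05` (the
  conventional small-world setting), then each edge oriented uniformly
  at random — structured but still non-hierarchical; edge count exactly
  `nk/2`.
* **Old→new preferential attachment** (`pa`): growth starts from `m`
  isolated seed nodes; each newcomer attaches to `m` distinct existing
  nodes with probability proportional to degree (the first newcomer
  therefore takes all seeds), and every edge is oriented from the older
  to the newer endpoint. The output is a DAG with every non-seed node at
  in-degree `m`, so rooting deletes exactly `m - 1` parents per non-seed
  node and the score is exactly `1/m` = `(n-m)/(m(n-m))`. This seeding
  was chosen over networkx's star-seeded variant precisely because it
  realises the `1/m` closed form exactly rather than asymptotically.
* Toy structures: balanced out-trees, the hub-plus-flipped-rim wheel
  (DAG, flow hierarchy 1, arborescence score 0.5 — the case separating
  cycle-based from arborescence-based measures), stars, cycles, a
  two-rooted toy DAG, and four hard-coded illustrative fixtures. Each
  fixture asserts its structural facts (edge counts, SCC contents,
  in-degree-0 sets) before being served; the fixtures are transcriptions
  pinned by those constraint sets, and any transcription satisfying them
  yields the same scores.

`sweep` reports mean ± sd of each measure over seeded replicates per
edge-count grid point (default: 100 nodes, 100 replicates); for `ws` and
`pa` each requested edge count maps to the nearest feasible parameter
(even `k`, integer `m`) and the realised count is reported.
`pa_er_ratio` divides preferential-attachment means by Erdős–Rényi means
measure-by-measure; an infinite ratio is reported as `inf` when the ER
mean is exactly 0.

### What the generators do and do not emulate

The random families reproduce the regimes in which the measures are
known to agree or disagree (no hierarchy, structured no-hierarchy,
hub-rooted hierarchy). They do not emulate real biological or social
networks: no reciprocity beyond chance, no community structure, no
degree–degree correlations beyond those the models imply. Tests passing
on them show the measures behave as analysed under these controlled
conditions, not that any particular real network will score similarly.

## Problem sizes in the test suite

The suite validates the closed-form identity on 1000 random graphs of up
to 10 nodes, the SCC oracle (transitive-closure mutual reachability) on
graphs of up to 8 nodes, the `1/m` law at n = 100 for m ∈ {2, 3, 5} over
20 seeds, the ER/WS low-score trend at 100 nodes / 500 edges over 20
replicates, the PA/ER ratio on a three-point edge grid with 10
replicates, and one 1000-replica null test on a 100-node, 500-edge
graph. Label-stability checks run 20 independent trials with 50-replica
ensembles — a scaled version of the 100-trial protocol that keeps the
same expected behaviour with comfortable margins.

## Known limitations

* The score is strict: on dense real networks most edges vanish in
  condensation, and the roots of the resulting forest can be large
  collapsed components whose internal order the method cannot resolve.
* The closeness heuristic picks *a* plausible parent, not a certified
  optimum; only the score, not the forest shape, is
  tie-break-invariant.
* Exact minimum agony for cyclic graphs is not implemented; cyclic
  agony comparisons require an external ranking.
* The double edge switch is a single-pass randomisation, not a mixed
  Markov chain with diagnostics; `|E|` successful swaps is the
  conventional budget, not a mixing guarantee.
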