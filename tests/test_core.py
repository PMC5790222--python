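"""Condensation, closeness rooting, and the arborescence score."""

import random
from fractions import Fraction

import pytest

from arbscore.core import (
    arborescence_score,
    component_identifier,
    condense,
    out_closeness,
    root_forest,
)
from arbscore.generators import (
    fixture_arborescence_example,
    fixture_dag_example,
    fixture_tree_example,
    fixture_worked_example,
    gen_cycle,
)
from arbscore.graph import DirectedGraph, is_arborescence_forest, is_dag

from conftest import graph_corpus


class TestCondense:
    def test_worked_example_collapses_to_ten_components(self):
        cd = condense(fixture_worked_example())
        assert cd.dag.n_nodes == 10
        assert is_dag(cd.dag)
        assert cd.members("scc:11") == {"11", "12", "13", "14"}
        assert cd.members("scc:6") == {"6", "7", "8"}

    def test_cycle_condenses_to_single_bare_node(self):
        cd = condense(gen_cycle(4))
        assert cd.dag.n_nodes == 1
        assert cd.dag.n_edges == 0

    def test_dag_is_condensation_fixed_point(self):
        g = fixture_dag_example()
        cd = condense(g)
        assert cd.dag.nodes == g.nodes
        assert cd.dag.edges == g.edges

    def test_parallel_inter_component_edges_merge(self):
        # two edges from the 2-cycle {a,b} into c become one condensed edge
        g = DirectedGraph.from_edges(
            [("a", "b"), ("b", "a"), ("a", "c"), ("b", "c")]
        )
        cd = condense(g)
        assert cd.dag.edges == {("scc:a", "c")}

    def test_self_loop_disappears_in_condensation(self):
        g = DirectedGraph.from_edges([("a", "a"), ("a", "b")])
        cd = condense(g)
        assert cd.dag.edges == {("a", "b")}

    def test_multi_member_identifier_is_prefixed(self):
        assert component_identifier(frozenset({"b", "a"})) == "scc:a"
        assert component_identifier(frozenset({"a"})) == "a"


class TestOutCloseness:
    def test_path_graph_values(self):
        g = DirectedGraph.from_edges([("0", "1"), ("1", "2")])
        c = out_closeness(g)
        assert c == {"0": pytest.approx(1 / 3), "1": 1.0, "2": 0.0}

    def test_star_hub_and_spokes(self):
        g = DirectedGraph.from_edges([("h", "a"), ("h", "b"), ("h", "c")])
        c = out_closeness(g)
        assert c["h"] == pytest.approx(1 / 3)
        assert c["a"] == c["b"] == c["c"] == 0.0

    def test_diamond_head_has_lowest_closeness(self):
        g = DirectedGraph.from_edges([("r", "a"), ("r", "b"), ("a", "b")])
        c = out_closeness(g)
        assert c == {"r": pytest.approx(0.5), "a": 1.0, "b": 0.0}

    def test_zero_exactly_for_leaves(self, small_corpus):
        for g in small_corpus:
            cd = condense(g)
            c = out_closeness(cd.dag)
            for node in cd.dag.nodes:
                assert (c[node] == 0.0) == (cd.dag.out_degree(node) == 0)


class TestRootForest:
    def test_tree_example_deletes_the_upward_edge(self):
        forest, roots, removed = root_forest(condense(fixture_tree_example()))
        assert removed == (("3", "2"),)
        assert roots == ("0", "3")
        assert is_arborescence_forest(forest)

    def test_lowest_closeness_parent_wins(self):
        cd = condense(DirectedGraph.from_edges([("r", "a"), ("r", "b"), ("a", "b")]))
        forest, roots, removed = root_forest(cd)
        assert forest.edges == {("r", "a"), ("r", "b")}
        assert removed == (("a", "b"),)
        assert roots == ("r",)

    def test_chain_is_left_untouched(self):
        cd = condense(DirectedGraph.from_edges([("0", "1"), ("1", "2")]))
        forest, roots, removed = root_forest(cd)
        assert removed == ()
        assert roots == ("0",)
        assert forest.n_edges == 2

    def test_cyclic_input_is_rejected(self):
        from arbscore.core import CondensedDAG
        from arbscore.graph import find_sccs

        g = gen_cycle(3)
        bogus = CondensedDAG(find_sccs(g), g, {0: "0"})
        with pytest.raises(ValueError, match="condense"):
            root_forest(bogus)

    def test_edge_count_is_nodes_minus_roots(self, small_corpus):
        for g in small_corpus:
            cd = condense(g)
            forest, roots, _ = root_forest(cd)
            assert forest.n_edges == cd.dag.n_nodes - len(roots)


class TestArborescenceScore:
    @pytest.mark.parametrize(
        "builder, expected",
        [
            (fixture_dag_example, Fraction(8, 10)),
            (fixture_tree_example, Fraction(7, 8)),
            (fixture_arborescence_example, Fraction(1)),
            (fixture_worked_example, Fraction(9, 20)),
        ],
    )
    def test_fixture_scores_are_exact(self, builder, expected):
        res = arborescence_score(builder())
        assert res.score_fraction == expected
        assert res.score == pytest.approx(float(expected))

    def test_cycle_scores_zero(self):
        assert arborescence_score(gen_cycle(6)).score == 0.0

    def test_worked_example_bookkeeping(self):
        res = arborescence_score(fixture_worked_example())
        assert res.n_nodes == 15
        assert res.n_edges == 20
        assert res.n_condensed_nodes == 10
        assert res.n_forest_edges == 9
        assert len(res.roots) == 1
        # 7 intra-component edges vanish in condensation
        assert len(res.removed_in_condensation) == 7
        assert is_arborescence_forest(res.forest)

    def test_empty_edge_set_is_an_error(self):
        g = DirectedGraph(frozenset({"a"}), frozenset())
        with pytest.raises(ValueError, match="empty edge set"):
            arborescence_score(g)

    def test_score_one_iff_already_a_forest(self, small_corpus):
        for g in (g for g in small_corpus if g.n_edges > 0):
            res = arborescence_score(g)
            assert (res.score == 1.0) == is_arborescence_forest(g)

    def test_closed_form_on_corpus(self, small_corpus):
        # score == (|V*| - #sources of condensed DAG) / |E|
        for g in (g for g in small_corpus if g.n_edges > 0):
            res = arborescence_score(g)
            cd = condense(g)
            z = sum(1 for n in cd.dag.nodes if cd.dag.in_degree(n) == 0)
            assert res.score_fraction == Fraction(cd.dag.n_nodes - z, g.n_edges)

    def test_label_permutation_never_changes_the_score(self):
        rng = random.Random(99)
        for g in graph_corpus(seed=3, size=30, n_max=7, p=0.35):
            if g.n_edges == 0:
                continue
            nodes = sorted(g.nodes)
            shuffled = nodes[:]
            rng.shuffle(shuffled)
            relabel = dict(zip(nodes, shuffled))
            h = DirectedGraph.from_edges(
                ((relabel[u], relabel[v]) for u, v in g.edges),
                nodes=relabel.values(),
            )
            a, b = arborescence_score(g), arborescence_score(h)
            assert a.score_fraction == b.score_fraction
            assert a.n_forest_edges == b.n_forest_edges
            assert len(a.roots) == len(b.roots)

    def test_adding_an_intra_scc_edge_strictly_lowers_the_score(self):
        g = DirectedGraph.from_edges(
            [("a", "b"), ("b", "c"), ("c", "a"), ("a", "d"), ("d", "e")]
        )
        before = arborescence_score(g)
        g2 = DirectedGraph.from_edges(sorted(g.edges) + [("b", "a")])
        after = arborescence_score(g2)
        assert after.n_forest_edges == before.n_forest_edges
        assert after.score < before.score

    def test_isolated_nodes_leave_the_score_unchanged(self):
        g = fixture_dag_example()
        with_iso = DirectedGraph.from_edges(g.edges, nodes=g.nodes | {"zz1", "zz2"})
        a, b = arborescence_score(g), arborescence_score(with_iso)
        assert a.score_fraction == b.score_fraction
        # each isolated node becomes its own root
        assert len(b.roots) == len(a.roots) + 2

    def test_forest_is_valid_on_corpus(self, small_corpus):
        for g in (g for g in small_corpus if g.n_edges > 0):
            assert is_arborescence_forest(arborescence_score(g).forest)
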