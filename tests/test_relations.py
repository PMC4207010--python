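"""Cross-edge counting, the permutation null, and the pathway landscape."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binom

from procmod import graphio, synth
from procmod.errors import ContractError
from procmod.graphio import PathwayAnnotation
from procmod.relations import (
    cross_edge_count,
    pathway_landscape,
    relation_significance,
    score_model_relations,
)
from procmod.segmentation import build_process_model
from tests.conftest import clique_graph


def complete_bipartite(na, nb):
    g = graphio.new_network()
    a = [f"a{i}" for i in range(na)]
    b = [f"b{i}" for i in range(nb)]
    for u in a:
        for v in b:
            g.add_edge(u, v)
    return g, set(a), set(b)


class TestCrossEdgeCount:
    def test_disconnected_components_count_zero(self, three_cliques):
        g, labels = three_cliques
        a = {n for n, m in labels.items() if m == 0}
        b = {n for n, m in labels.items() if m == 1}
        assert cross_edge_count(g, a, b) == 0

    def test_complete_bipartite_counts_all_pairs(self):
        g, a, b = complete_bipartite(2, 3)
        assert cross_edge_count(g, a, b) == 6

    def test_overlapping_sets_rejected(self):
        g, a, b = complete_bipartite(2, 3)
        with pytest.raises(ContractError):
            cross_edge_count(g, a, b | {next(iter(a))})

    def test_symmetry_and_within_set_edge_invariance(self):
        g, a, b = complete_bipartite(3, 3)
        assert cross_edge_count(g, a, b) == cross_edge_count(g, b, a)
        before = cross_edge_count(g, a, b)
        g.add_edge("a0", "a1")  # internal to set_a
        assert cross_edge_count(g, a, b) == before


class TestRelationSignificance:
    def test_zero_observed_gives_p_one(self):
        g = graphio.new_network()
        g.add_nodes_from(f"n{i}" for i in range(10))
        g.add_edge("n8", "n9")
        stat = relation_significance(g, {"n0"}, {"n1"}, g.nodes(), n_perm=99, seed=1)
        assert stat.observed == 0
        assert stat.p_empirical == 1.0

    def test_complete_graph_null_is_degenerate(self):
        g = clique_graph(10)
        nodes = sorted(g.nodes())
        stat = relation_significance(
            g, set(nodes[:2]), set(nodes[2:4]), nodes, n_perm=199, seed=2)
        assert stat.observed == 4
        assert stat.null_sd == 0.0
        assert stat.z is None
        assert stat.p_empirical == 1.0

    def test_planted_bridges_are_significant(self):
        """Two 8-cliques joined by 5 bridges in a sparse 100-node background.

        The bridge count (5) far exceeds the null expectation (~1.0), but the
        cliques themselves sit in the sampling universe, so null draws that
        capture several members of one clique in both sets put ~1% mass at or
        above the observed count (large-sample permutation estimate of the
        exact tail: 0.0101); with the add-one correction the empirical p
        therefore lands just above 0.01.
        """
        rng = np.random.default_rng(42)
        g = clique_graph(8, 8)
        names = [f"bg{i:03d}" for i in range(100)]
        g.add_nodes_from(names)
        for u, v in itertools.combinations(names, 2):
            if rng.random() < 0.01:
                g.add_edge(u, v)
        a = {f"c0_{i}" for i in range(8)}
        b = {f"c1_{i}" for i in range(8)}
        for i in range(5):
            g.add_edge(f"c0_{i}", f"c1_{i}")
        stat = relation_significance(g, a, b, g.nodes(), n_perm=999, seed=3)
        assert stat.observed == 5
        assert stat.z > 3
        assert stat.p_empirical <= 0.02

    def test_reproducible_to_the_last_digit(self):
        g = clique_graph(6, 6)
        a = {f"c0_{i}" for i in range(3)}
        b = {f"c1_{i}" for i in range(3)}
        s1 = relation_significance(g, a, b, g.nodes(), n_perm=199, seed=9)
        s2 = relation_significance(g, a, b, g.nodes(), n_perm=199, seed=9)
        assert (s1.observed, s1.null_mean, s1.null_sd, s1.p_empirical) == (
            s2.observed, s2.null_mean, s2.null_sd, s2.p_empirical)

    def test_p_never_zero(self):
        g, a, b = complete_bipartite(4, 4)
        stat = relation_significance(g, a, b, g.nodes(), n_perm=49, seed=0)
        assert stat.p_empirical > 0

    def test_universe_too_small_rejected(self):
        g, a, b = complete_bipartite(3, 3)
        with pytest.raises(ContractError):
            relation_significance(g, a, b, list(a | b)[:5], n_perm=9, seed=0)

    def test_null_calibration_is_super_uniform(self):
        """For random disjoint sets the p-value behaves like (or conservatively
        exceeds) a uniform: the rejection rate at 0.05 over 120 runs stays
        inside the exact binomial 99% band."""
        rng = np.random.default_rng(7)
        g = graphio.new_network()
        names = [f"n{i:02d}" for i in range(50)]
        g.add_nodes_from(names)
        for u, v in itertools.combinations(names, 2):
            if rng.random() < 0.12:
                g.add_edge(u, v)
        n_runs, hits = 120, 0
        for r in range(n_runs):
            draw = rng.permutation(names)
            a, b = set(draw[:7]), set(draw[7:14])
            stat = relation_significance(g, a, b, names, n_perm=199, seed=1000 + r)
            hits += stat.p_empirical <= 0.05
        lo, hi = binom.interval(0.99, n_runs, 0.05)
        assert lo <= hits <= hi


class TestModelRelations:
    def test_single_segment_has_no_relations(self):
        g = clique_graph(5)
        model = build_process_model(g, set(g.nodes()))
        score_model_relations(model, n_perm=19, seed=0)
        assert model.relations == []

    def test_three_segments_give_three_pairs(self, three_cliques):
        g, _ = three_cliques
        model = build_process_model(g, set(g.nodes()))
        score_model_relations(model, n_perm=19, seed=0)
        assert len(model.relations) == 3

    def test_only_the_bridged_pair_is_significant(self):
        """Heavy bridging between two of three modules; alpha 0.05 after BH.

        The bridged cliques differ in density (K10 vs K6) so the VWP
        threshold keeps them separate segments; a sparse path background
        provides the sampling universe without forming segments of its own.
        """
        g = clique_graph(10, 6, 7)
        for i in range(6):
            g.add_edge(f"c0_{i}", f"c1_{i % 6}")
        path = [f"p{i:03d}" for i in range(200)]
        for u, v in zip(path, path[1:]):
            g.add_edge(u, v)
        model = build_process_model(g, set(g.nodes()))
        assert sorted(len(s) for s in model.segments) == [6, 7, 10]
        score_model_relations(model, n_perm=499, seed=4, alpha=0.05)
        seg_of = {len(s.genes): s.segment_id for s in model.segments}
        bridged = frozenset({seg_of[10], seg_of[6]})
        flagged = {frozenset({r.id_a, r.id_b}) for r in model.relations if r.significant}
        assert flagged == {bridged}


class TestPathwayLandscape:
    def test_disjoint_unconnected_pathways_emit_nothing(self, three_cliques):
        g, labels = three_cliques
        pws = [
            PathwayAnnotation(f"P{m}", "", frozenset(n for n, lab in labels.items() if lab == m))
            for m in range(2)
        ]
        assert pathway_landscape(pws, g) == []

    def test_shared_and_cross_counts_on_hand_fixture(self):
        # 9 genes: pathways share s1,s2; 3 edges between the non-shared parts
        g = graphio.new_network()
        g.add_nodes_from([f"x{i}" for i in range(4)] + [f"y{i}" for i in range(3)]
                         + ["s1", "s2"])
        g.add_edge("x0", "y0")
        g.add_edge("x1", "y1")
        g.add_edge("x2", "y2")
        g.add_edge("s1", "x0")  # incident to a shared gene: must not count
        pa = PathwayAnnotation("A", "", frozenset({"x0", "x1", "x2", "x3", "s1", "s2"}))
        pb = PathwayAnnotation("B", "", frozenset({"y0", "y1", "y2", "s1", "s2"}))
        (rel,) = pathway_landscape([pa, pb], g)
        assert rel.shared_genes == 2
        assert rel.cross_edges == 3

    def test_no_self_relations(self, three_cliques):
        g, labels = three_cliques
        pw = PathwayAnnotation("P0", "", frozenset(labels))
        assert pathway_landscape([pw], g) == []
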