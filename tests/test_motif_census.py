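import itertools

import numpy as np
import pytest

from weavenet.graph_model import MixedGraph
from weavenet.motif_census import (
    MotifClass,
    background_distribution,
    census,
    classify_triple,
    enrichment,
    sample_connected_subgraph,
)
from weavenet.synthetic_fixtures import plant_motifs

from _oracles import brute_force_census, motif_rule_table
from conftest import random_mixed_graph


def build_triple_graph(ppi_pairs, reg_pairs):
    g = MixedGraph()
    for n in ("A", "B", "C"):
        g.add_protein(n)
    for a, b in ppi_pairs:
        g.add_ppi_edge(a, b)
    for a, b in reg_pairs:
        g.add_reg_edge(a, b)
    return g


class TestClassifyTriple:
    def test_ppi_triangle_is_protein_clique(self):
        g = build_triple_graph([("A", "B"), ("A", "C"), ("B", "C")], [])
        assert classify_triple(g, "A", "B", "C") == {MotifClass.PROTEIN_CLIQUE}

    def test_pure_regulatory_ffl(self):
        g = build_triple_graph([], [("A", "B"), ("A", "C"), ("B", "C")])
        assert classify_triple(g, "A", "B", "C") == {MotifClass.FEED_FORWARD_LOOP}

    def test_mfl_not_misclassified_as_ffl(self):
        # TF pair physically interacts: mixed feedback loop, never FFL
        g = build_triple_graph([("A", "B")],
                               [("A", "B"), ("A", "C"), ("B", "C")])
        assert classify_triple(g, "A", "B", "C") == {MotifClass.MIXED_FEEDBACK_LOOP}

    def test_interacting_coregulators(self):
        g = build_triple_graph([("A", "B")], [("A", "C"), ("B", "C")])
        assert classify_triple(g, "A", "B", "C") == \
            {MotifClass.INTERACTING_COREGULATORS}

    def test_coregulated_interactors(self):
        g = build_triple_graph([("B", "C")], [("A", "B"), ("A", "C")])
        assert classify_triple(g, "A", "B", "C") == \
            {MotifClass.COREGULATED_INTERACTORS}

    def test_clique_tallies_alongside_regulatory_class(self):
        g = build_triple_graph([("A", "B"), ("A", "C"), ("B", "C")],
                               [("A", "B"), ("A", "C"), ("B", "C")])
        assert classify_triple(g, "A", "B", "C") == \
            {MotifClass.PROTEIN_CLIQUE, MotifClass.MIXED_FEEDBACK_LOOP}

    def test_non_distinct_nodes_raise(self):
        g = build_triple_graph([("A", "B")], [])
        with pytest.raises(ValueError):
            classify_triple(g, "A", "A", "B")

    def test_relabeling_symmetry(self):
        g = build_triple_graph([("A", "B")], [("A", "C"), ("B", "C")])
        expected = classify_triple(g, "A", "B", "C")
        for order in itertools.permutations("ABC"):
            assert classify_triple(g, *order) == expected

    def test_exhaustive_rule_table(self):
        """All 2^3 PPI x 2^6 regulatory configurations match the rule table."""
        ppi_pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        reg_pairs = [(x, y) for x, y in itertools.permutations("ABC", 2)]
        for ppi_mask in range(8):
            for reg_mask in range(64):
                ppi = [ppi_pairs[i] for i in range(3) if ppi_mask >> i & 1]
                reg = [reg_pairs[i] for i in range(6) if reg_mask >> i & 1]
                g = build_triple_graph(ppi, reg)
                got = {c.value for c in classify_triple(g, "A", "B", "C")}
                expected = motif_rule_table(
                    ("A", "B") in ppi, ("A", "C") in ppi, ("B", "C") in ppi,
                    set(reg))
                assert got == expected, (ppi, reg)


class TestCensus:
    def test_four_clique_gives_four_cliques(self):
        g = MixedGraph()
        for a, b in itertools.combinations("wxyz", 2):
            g.add_ppi_edge(a, b)
        assert census(g)[MotifClass.PROTEIN_CLIQUE] == 4

    def test_empty_graph_all_zeros(self):
        g = MixedGraph()
        for n in "abc":
            g.add_protein(n)
        assert all(v == 0 for v in census(g).values())

    def test_autoregulation_ignored(self):
        g = build_triple_graph([], [("A", "B"), ("A", "C"), ("B", "C"),
                                    ("A", "A")])
        assert census(g)[MotifClass.FEED_FORWARD_LOOP] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_triples(self, seed):
        rng = np.random.default_rng(seed)
        g = random_mixed_graph(rng, int(rng.integers(6, 14)))
        got = {c.value: v for c, v in census(g).items()}
        expected = brute_force_census(
            sorted(g.nodes),
            {frozenset(e) for e in g.ppi_edges()},
            set(g.reg_edges()))
        assert got == expected

    def test_subset_census(self):
        g = MixedGraph()
        for a, b in itertools.combinations("wxyz", 2):
            g.add_ppi_edge(a, b)
        assert census(g, {"w", "x", "y"})[MotifClass.PROTEIN_CLIQUE] == 1

    def test_adding_ppi_edge_never_decreases_cliques(self):
        rng = np.random.default_rng(8)
        g = random_mixed_graph(rng, 10)
        before = census(g)[MotifClass.PROTEIN_CLIQUE]
        nodes = sorted(g.nodes)
        for a, b in itertools.combinations(nodes, 2):
            if not g.has_ppi_edge(a, b):
                g.add_ppi_edge(a, b)
                break
        assert census(g)[MotifClass.PROTEIN_CLIQUE] >= before


class TestPlantedMotifs:
    def empty_graph(self, n=40):
        g = MixedGraph()
        for i in range(n):
            g.add_protein(f"p{i:02d}")
        return g

    def test_planted_ffls_found_exactly(self):
        g = self.empty_graph(9)
        plant_motifs(g, MotifClass.FEED_FORWARD_LOOP, 3, seed=1)
        counts = census(g)
        assert counts[MotifClass.FEED_FORWARD_LOOP] == 3
        assert sum(counts.values()) == 3

    def test_planted_mfls_not_counted_as_ffls(self):
        g = self.empty_graph(9)
        plant_motifs(g, MotifClass.MIXED_FEEDBACK_LOOP, 2, seed=2)
        counts = census(g)
        assert counts[MotifClass.MIXED_FEEDBACK_LOOP] == 2
        assert counts[MotifClass.FEED_FORWARD_LOOP] == 0

    def test_one_of_each_class(self):
        g = self.empty_graph(20)
        for cls in MotifClass:
            plant_motifs(g, cls, 1, seed=hash(cls.value) % 1000)
        counts = census(g)
        assert all(counts[cls] == 1 for cls in MotifClass)

    def test_insufficient_room_raises(self):
        g = self.empty_graph(5)
        with pytest.raises(ValueError):
            plant_motifs(g, MotifClass.PROTEIN_CLIQUE, 2, seed=0)


class TestBackgroundAndEnrichment:
    def test_pure_ffl_background_proportion_one(self):
        g = build_triple_graph([], [("A", "B"), ("A", "C"), ("B", "C")])
        counts, props = background_distribution(g)
        assert props[MotifClass.FEED_FORWARD_LOOP] == 1.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(17)
        g = random_mixed_graph(rng, 14)
        counts, props = background_distribution(g)
        if sum(counts.values()):
            assert abs(sum(props.values()) - 1.0) < 1e-12

    def test_self_comparison_z_near_zero(self):
        rng = np.random.default_rng(3)
        g = random_mixed_graph(rng, 12, ppi_p=0.4, reg_p=0.2)
        counts = census(g)
        report = enrichment(counts, g, g.number_of_nodes(), reps=50, seed=5)
        for cls, s in report.per_class.items():
            if s.null_sd > 0:
                assert abs(s.z) < 1e-9  # null == observed when sampling whole graph
            else:
                assert s.z == 0.0
            assert s.p == 1.0 or s.null_sd == 0

    def test_degenerate_null_zero_observed(self):
        g = MixedGraph()
        for a, b in [("a", "b"), ("b", "c"), ("c", "d")]:
            g.add_ppi_edge(a, b)
        report = enrichment({cls: 0 for cls in MotifClass}, g, 3, reps=30, seed=0)
        for s in report.per_class.values():
            assert s.p == 1.0
            assert s.z == 0.0

    def test_planted_ffl_cluster_enriched(self):
        # dense FFL cluster queried against a sparse background
        rng = np.random.default_rng(11)
        g = MixedGraph()
        for i in range(60):
            g.add_protein(f"p{i:02d}")
        nodes = sorted(g.nodes)
        # sparse background chain so snowball sampling can traverse
        for a, b in zip(nodes, nodes[1:]):
            g.add_ppi_edge(a, b)
        cluster = nodes[:8]
        for x, y, z in itertools.combinations(cluster, 3):
            g.add_reg_edge(x, y)
            g.add_reg_edge(x, z)
            g.add_reg_edge(y, z)
        sub_counts = census(g, set(cluster))
        report = enrichment(sub_counts, g, len(cluster), reps=199, seed=13)
        assert report.per_class[MotifClass.FEED_FORWARD_LOOP].p <= 0.05

    def test_subgraph_sampler_connected_and_sized(self):
        import networkx as nx
        from weavenet.subnetwork_query import traversal_view
        from weavenet.graph_model import EdgeTypeFilter
        rng_graph = np.random.default_rng(21)
        g = random_mixed_graph(rng_graph, 15, ppi_p=0.3)
        view = traversal_view(g, EdgeTypeFilter.MIXED)
        rng = np.random.default_rng(0)
        for _ in range(20):
            sample = sample_connected_subgraph(g, 5, rng)
            assert len(sample) == 5
            assert nx.is_connected(view.subgraph(sample))

    def test_oversized_subnetwork_raises(self, toy_graph):
        with pytest.raises(ValueError):
            enrichment({}, toy_graph, 100, reps=10, seed=0)
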