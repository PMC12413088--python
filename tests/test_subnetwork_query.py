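import numpy as np
import pytest

from weavenet.graph_model import EdgeTypeFilter, MixedGraph
from weavenet.ontology import AnnotationSet
from weavenet.subnetwork_query import (
    QueryMode,
    QuerySpec,
    k_unique_nodes,
    k_unique_paths,
    requery,
    run_query,
    traversal_view,
)

from _oracles import all_simple_paths_to_targets, bfs_distances
from conftest import random_mixed_graph

TERM = "GO:0000003"


def annotate(*proteins):
    annots = AnnotationSet()
    for p in proteins:
        annots.add(p, TERM)
    return annots


def view_adj(graph, flt):
    view = traversal_view(graph, flt)
    return {n: set(view.neighbors(n)) for n in view.nodes}


class TestTraversalView:
    def test_regulatory_edges_bidirectional(self):
        g = MixedGraph()
        g.add_reg_edge("A", "B")
        view = traversal_view(g, EdgeTypeFilter.REGULATORY)
        assert set(view.neighbors("A")) == {"B"}
        assert set(view.neighbors("B")) == {"A"}

    def test_physical_filter_hides_reg_edges(self, toy_graph):
        view = traversal_view(toy_graph, EdgeTypeFilter.PHYSICAL)
        assert set(view.neighbors("x")) == {"a"}
        assert set(view.neighbors("tf")) == set()

    @pytest.mark.parametrize("seed", range(4))
    def test_mixed_view_is_union(self, seed):
        g = random_mixed_graph(np.random.default_rng(seed), 10)
        phys = view_adj(g, EdgeTypeFilter.PHYSICAL)
        reg = view_adj(g, EdgeTypeFilter.REGULATORY)
        mixed = view_adj(g, EdgeTypeFilter.MIXED)
        for n in g.nodes:
            assert mixed[n] == phys[n] | reg[n]


class TestKUniquePaths:
    def test_single_adjacent_annotated_node(self, toy_graph):
        spec = QuerySpec(source="s", term=TERM, k=1)
        res = k_unique_paths(toy_graph, annotate("b"), spec)
        assert res.paths == [("s", "b")]
        assert res.roles == {"s": "source", "b": "annotated"}

    def test_exhaustion_returns_all_without_padding(self, toy_graph):
        spec = QuerySpec(source="s", term=TERM, k=50)
        res = k_unique_paths(toy_graph, annotate("x"), spec)
        # all simple s->x paths in the mixed toy graph
        assert all(p[0] == "s" and p[-1] == "x" for p in res.paths)
        assert len(res.paths) == len(set(res.paths)) < 50

    def test_multiple_paths_may_share_terminal(self):
        g = MixedGraph()
        for mid in ("m1", "m2", "m3"):
            g.add_ppi_edge("s", mid)
            g.add_ppi_edge(mid, "t")
        res = k_unique_paths(g, annotate("t"), QuerySpec(source="s", term=TERM, k=3))
        assert [p[-1] for p in res.paths] == ["t", "t", "t"]

    def test_annotated_source_excluded_from_targets(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "t")
        res = k_unique_paths(g, annotate("s", "t"),
                             QuerySpec(source="s", term=TERM, k=5))
        assert res.paths == [("s", "t")]

    def test_parallel_edges_single_node_sequence(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "t")
        g.add_reg_edge("s", "t")
        res = k_unique_paths(g, annotate("t"), QuerySpec(source="s", term=TERM, k=5))
        assert res.paths == [("s", "t")]
        assert set(res.edges) == {("s", "t", "physical"), ("s", "t", "regulatory")}

    def test_unreachable_gives_empty_with_diagnostic(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "a")
        g.add_protein("t")
        res = k_unique_paths(g, annotate("t"), QuerySpec(source="s", term=TERM, k=2))
        assert res.paths == []
        assert "cannot reach" in res.diagnostic

    def test_unknown_source_raises(self, toy_graph):
        with pytest.raises(KeyError):
            k_unique_paths(toy_graph, annotate("x"),
                           QuerySpec(source="ghost", term=TERM, k=1))

    def test_paths_sorted_by_length_then_lex(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "b")
        g.add_ppi_edge("s", "a")
        g.add_ppi_edge("a", "t")
        g.add_ppi_edge("b", "t")
        res = k_unique_paths(g, annotate("t"), QuerySpec(source="s", term=TERM, k=2))
        assert res.paths == [("s", "a", "t"), ("s", "b", "t")]

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("flt", list(EdgeTypeFilter))
    def test_matches_exhaustive_enumeration(self, seed, flt):
        rng = np.random.default_rng(seed)
        g = random_mixed_graph(rng, 10)
        nodes = sorted(g.nodes)
        source = nodes[0]
        targets = set(nodes[-3:])
        annots = annotate(*targets)
        k = int(rng.integers(1, 7))
        spec = QuerySpec(source=source, term=TERM, k=k, filter=flt)
        res = k_unique_paths(g, annots, spec)
        oracle = all_simple_paths_to_targets(view_adj(g, flt), source,
                                             targets - {source})[:k]
        assert res.paths == oracle

    def test_prefix_stability(self):
        g = random_mixed_graph(np.random.default_rng(42), 12)
        nodes = sorted(g.nodes)
        annots = annotate(*nodes[-4:])
        small = k_unique_paths(g, annots, QuerySpec(source=nodes[0], term=TERM, k=4))
        big = k_unique_paths(g, annots, QuerySpec(source=nodes[0], term=TERM, k=9))
        assert big.paths[:len(small.paths)] == small.paths


class TestKUniqueNodes:
    def test_two_neighbors_at_distance_one(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "a")
        g.add_ppi_edge("s", "b")
        res = k_unique_nodes(g, annotate("a", "b"),
                             QuerySpec(source="s", term=TERM, k=2,
                                       mode=QueryMode.K_UNIQUE_NODES))
        assert res.paths == [("s", "a"), ("s", "b")]

    def test_k1_selects_closest(self):
        g = MixedGraph()
        g.add_ppi_edge("s", "near")
        g.add_ppi_edge("s", "m1")
        g.add_ppi_edge("m1", "m2")
        g.add_ppi_edge("m2", "far")
        res = k_unique_nodes(g, annotate("near", "far"),
                             QuerySpec(source="s", term=TERM, k=1,
                                       mode=QueryMode.K_UNIQUE_NODES))
        assert [p[-1] for p in res.paths] == ["near"]

    @pytest.mark.parametrize("seed", range(10))
    def test_selection_matches_distance_ranking(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_mixed_graph(rng, 11)
        nodes = sorted(g.nodes)
        source = nodes[0]
        targets = set(nodes[-4:]) - {source}
        k = int(rng.integers(1, 5))
        spec = QuerySpec(source=source, term=TERM, k=k,
                         mode=QueryMode.K_UNIQUE_NODES)
        res = k_unique_nodes(g, annotate(*targets), spec)
        dist = bfs_distances(view_adj(g, EdgeTypeFilter.MIXED), source)
        ranked = sorted((dist[t], t) for t in targets if t in dist)
        expected = [t for _, t in ranked[:k]]
        assert sorted(p[-1] for p in res.paths) == sorted(expected)
        # each witness path is a shortest path
        for p in res.paths:
            assert len(p) - 1 == dist[p[-1]]

    def test_selected_never_farther_than_unselected(self):
        g = random_mixed_graph(np.random.default_rng(5), 12)
        nodes = sorted(g.nodes)
        targets = set(nodes[-5:])
        spec = QuerySpec(source=nodes[0], term=TERM, k=2,
                         mode=QueryMode.K_UNIQUE_NODES)
        res = k_unique_nodes(g, annotate(*targets), spec)
        dist = bfs_distances(view_adj(g, EdgeTypeFilter.MIXED), nodes[0])
        chosen = {p[-1] for p in res.paths}
        unchosen = {t for t in targets if t in dist and t not in chosen
                    and t != nodes[0]}
        if res.paths and unchosen:
            assert max(dist[c] for c in chosen) <= min(dist[u] for u in unchosen)


class TestRequery:
    def test_same_source_idempotent(self, toy_graph):
        spec = QuerySpec(source="s", term=TERM, k=5)
        res = run_query(toy_graph, annotate("x", "b"), spec)
        again = requery(res, "s", toy_graph, annotate("x", "b"))
        assert again.paths == res.paths

    def test_requery_outside_result_raises(self, toy_graph):
        res = run_query(toy_graph, annotate("b"), QuerySpec(source="s", term=TERM, k=1))
        with pytest.raises(ValueError):
            requery(res, "tf", toy_graph, annotate("b"))

    def test_requery_from_annotated_terminal_excludes_itself(self, toy_graph):
        annots = annotate("x", "b")
        res = run_query(toy_graph, annots, QuerySpec(source="s", term=TERM, k=5))
        assert "b" in res.nodes
        re = requery(res, "b", toy_graph, annots)
        assert all(p[0] == "b" and p[-1] == "x" for p in re.paths)

    @pytest.mark.parametrize("seed", range(5))
    def test_requery_equals_fresh_query(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = random_mixed_graph(rng, 10)
        nodes = sorted(g.nodes)
        annots = annotate(*nodes[-3:])
        res = run_query(g, annots, QuerySpec(source=nodes[0], term=TERM, k=4))
        if not res.paths:
            pytest.skip("disconnected instance")
        pick = sorted(res.nodes)[1]
        re = requery(res, pick, g, annots)
        fresh = run_query(g, annots, QuerySpec(source=pick, term=TERM, k=4))
        assert re.paths == fresh.paths


def test_mixed_reachability_superset(toy_graph):
    import networkx as nx
    mixed = traversal_view(toy_graph, EdgeTypeFilter.MIXED)
    for flt in (EdgeTypeFilter.PHYSICAL, EdgeTypeFilter.REGULATORY):
        single = traversal_view(toy_graph, flt)
        reach_single = nx.node_connected_component(single, "s")
        reach_mixed = nx.node_connected_component(mixed, "s")
        assert reach_single <= reach_mixed
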