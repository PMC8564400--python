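import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexconn.metrics import (
    UNREACHABLE,
    classify_hubs,
    network_summary,
    node_metrics,
    shortest_paths,
)

from .conftest import graph_from_adj, graph_from_edges, random_graph
from .oracles import metrics_oracle


def _all_digraphs(n):
    """Every labeled simple digraph on n nodes, as adjacency matrices."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in range(1 << len(pairs)):
        adj = np.zeros((n, n), dtype=bool)
        for b, (i, j) in enumerate(pairs):
            if bits >> b & 1:
                adj[i, j] = True
        yield adj


class TestShortestPaths:
    def test_directed_path(self):
        g = graph_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        st_ = shortest_paths(g)
        i = {n: k for k, n in enumerate(st_.order)}
        assert st_.dist[i[1], i[3]] == 2 and st_.sigma[i[1], i[3]] == 1
        assert st_.dist[i[3], i[1]] == UNREACHABLE

    def test_diamond_two_shortest_paths(self):
        g = graph_from_edges([1, 2, 3, 4], [(1, 2), (1, 3), (2, 4), (3, 4)])
        st_ = shortest_paths(g)
        i = {n: k for k, n in enumerate(st_.order)}
        assert st_.sigma[i[1], i[4]] == 2
        assert st_.sigma_through(i[1], i[4], i[2]) == 1
        assert st_.sigma_through(i[1], i[4], i[3]) == 1

    def test_diagonal_is_zero(self):
        g = graph_from_edges(range(5), [(0, 1), (1, 2), (3, 4)])
        st_ = shortest_paths(g)
        assert (np.diag(st_.dist) == 0).all()


class TestNodeMetrics:
    def test_isolated_node_closeness_zero(self):
        g = graph_from_edges([1], [])
        m = node_metrics(g)
        assert m[1].closeness == 0.0
        assert m[1].eccentricity == 0

    def test_star_hub_closeness_one(self):
        """A driver one hop from its whole reachable set has closeness 1."""
        g = graph_from_edges("habc", [("h", "a"), ("h", "b"), ("h", "c")])
        m = node_metrics(g)
        assert m["h"].closeness == pytest.approx(1.0)
        assert m["a"].closeness == 0.0

    def test_chain_betweenness_and_eccentricity(self):
        g = graph_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        m = node_metrics(g)
        assert m[2].betweenness == pytest.approx(1.0)
        assert m[1].betweenness == m[3].betweenness == 0.0
        assert m[1].eccentricity == 2 and m[2].eccentricity == 1 and m[3].eccentricity == 0

    def test_exhaustive_oracle_small_graphs(self):
        """BFS/sigma metrics equal brute-force path enumeration, all n ≤ 4."""
        for n in (2, 3, 4):
            for adj in _all_digraphs(n):
                g = graph_from_adj(adj)
                m = node_metrics(g)
                ecc, clos, betw = metrics_oracle(adj)
                for i in range(n):
                    assert m[i].eccentricity == ecc[i], adj
                    assert m[i].closeness == pytest.approx(clos[i]), adj
                    assert m[i].betweenness == pytest.approx(betw[i]), adj

    def test_oracle_and_networkx_on_five_node_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(150):
            adj = rng.random((5, 5)) < rng.uniform(0.1, 0.7)
            np.fill_diagonal(adj, False)
            g = graph_from_adj(adj)
            m = node_metrics(g)
            ecc, clos, betw = metrics_oracle(adj)
            G = nx.from_numpy_array(adj.astype(int), create_using=nx.DiGraph)
            nx_betw = nx.betweenness_centrality(G, normalized=False)
            for i in range(5):
                assert m[i].eccentricity == ecc[i]
                assert m[i].closeness == pytest.approx(clos[i])
                assert m[i].betweenness == pytest.approx(betw[i])
                assert m[i].betweenness == pytest.approx(nx_betw[i])

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 12))
    def test_degree_conservation(self, seed, n):
        g = random_graph(np.random.default_rng(seed), n, 0.3)
        m = node_metrics(g)
        assert sum(v.k_in for v in m.values()) == g.n_edges
        assert sum(v.k_out for v in m.values()) == g.n_edges

    def test_betweenness_zero_at_diameter_one(self):
        n = 6
        edges = [(i, j) for i in range(n) for j in range(n) if i != j]
        m = node_metrics(graph_from_edges(range(n), edges))
        assert all(v.betweenness == 0.0 for v in m.values())

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_transpose_swaps_degrees_keeps_betweenness_multiset(self, seed):
        g = random_graph(np.random.default_rng(seed), 8, 0.3)
        m = node_metrics(g)
        mt = node_metrics(g.transpose())
        for node in g.nodes:
            assert m[node].k_in == mt[node].k_out
            assert m[node].k_out == mt[node].k_in
        fwd = sorted(round(v.betweenness, 9) for v in m.values())
        bwd = sorted(round(v.betweenness, 9) for v in mt.values())
        assert fwd == bwd


class TestNetworkSummary:
    def test_density_per_node_budget(self):
        g = graph_from_edges(range(4), [(0, 1), (2, 3)])
        s = network_summary(g)
        assert s.density == pytest.approx(0.5)
        assert s.density_std == pytest.approx(2 / 12)

    def test_edgeless_graph(self):
        s = network_summary(graph_from_edges(range(5), []))
        assert s.density == 0.0
        assert s.radius is None and s.diameter is None

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            network_summary(graph_from_edges([], []))

    def test_radius_le_diameter(self):
        g = graph_from_edges(range(5), [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)])
        s = network_summary(g)
        assert s.radius <= s.diameter


class TestClassifyHubs:
    def test_high_in_degree_is_integrator(self):
        edges = [(i, 9) for i in range(6)]
        g = graph_from_edges(range(10), edges)
        m = classify_hubs(node_metrics(g))
        assert "integrator_hub" in m[9].tags
        assert m[9].k_in == 6

    def test_high_out_degree_with_top_closeness_is_pacemaker(self):
        edges = [(9, i) for i in range(6)]
        g = graph_from_edges(range(10), edges)
        m = classify_hubs(node_metrics(g))
        assert "distributor_hub" in m[9].tags
        assert "pacemaker" in m[9].tags
        assert m[9].closeness == pytest.approx(1.0)

    def test_edgeless_graph_untagged(self):
        m = classify_hubs(node_metrics(graph_from_edges(range(6), [])))
        assert all(not v.tags for v in m.values())

    def test_bridge_node_is_bottleneck(self):
        # two fans joined through node 4: all 0..3 → 4 → 5..8
        edges = [(i, 4) for i in range(4)] + [(4, j) for j in range(5, 9)]
        g = graph_from_edges(range(9), edges)
        m = classify_hubs(node_metrics(g))
        assert "bottleneck" in m[4].tags
        assert "connector" in m[4].tags

    def test_thresholds_configurable(self):
        edges = [(9, i) for i in range(3)]
        g = graph_from_edges(range(10), edges)
        m = classify_hubs(node_metrics(g), {"deg_hi": 3})
        assert "distributor_hub" in m[9].tags
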