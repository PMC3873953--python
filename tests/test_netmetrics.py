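import numpy as np
import pytest

import oracles
from dtfnet.netmetrics import (
    build_network,
    clustering_coefficient,
    global_efficiency,
    network_density,
    network_metrics,
)


def complete_matrix(n, value=0.5):
    w = np.full((n, n), value)
    np.fill_diagonal(w, 0.0)
    return w


class TestBuildNetwork:
    def test_zero_matrix_has_no_edges(self):
        net = build_network(np.zeros((5, 5)), 0.1)
        assert net.n_edges == 0

    def test_full_16_node_network_has_240_edges(self):
        net = build_network(complete_matrix(16), 0.1)
        assert net.n_edges == 240

    def test_edge_count_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        w = oracles.random_weight_matrix(rng, 8)
        t = 0.4
        net = build_network(w, t)
        brute = sum(
            1 for i in range(8) for j in range(8) if i != j and w[i, j] > t
        )
        assert net.n_edges == brute

    def test_median_threshold_splits_off_diagonal_in_half(self):
        rng = np.random.default_rng(3)
        w = oracles.random_weight_matrix(rng, 6)
        net = build_network(w, "median")
        assert net.n_edges == 15  # half of 30 off-diagonal entries

    def test_negative_entries_rejected(self):
        w = complete_matrix(4)
        w[0, 1] = -0.1
        with pytest.raises(ValueError, match="negative"):
            build_network(w, 0.1)

    def test_nonzero_diagonal_rejected(self):
        w = complete_matrix(4)
        w[2, 2] = 0.3
        with pytest.raises(ValueError, match="diagonal"):
            build_network(w, 0.1)


class TestClustering:
    def test_complete_digraph_is_one(self):
        net = build_network(complete_matrix(4), 0.1)
        assert clustering_coefficient(net) == pytest.approx(1.0)

    def test_directed_star_is_zero(self):
        # hub (node 0) drives all leaves; no leaf-leaf edges
        w = np.zeros((5, 5))
        w[1:, 0] = 0.9  # sink rows 1..4 receive from source 0
        net = build_network(w, 0.1)
        assert clustering_coefficient(net) == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_digraphs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(2, 6)
            w = oracles.random_weight_matrix(rng, n)
            t = float(rng.uniform(0.2, 0.8))
            net = build_network(w, t)
            assert clustering_coefficient(net) == pytest.approx(
                oracles.clustering_bruteforce(net.binary_adj), abs=1e-12
            )


class TestDensity:
    def test_complete_graph(self):
        assert network_density(build_network(complete_matrix(6), 0.1)) == 1.0

    def test_empty_graph(self):
        assert network_density(build_network(np.zeros((6, 6)), 0.1)) == 0.0

    def test_half_filled_16_node_graph(self):
        w = np.zeros((16, 16))
        idx = [(i, j) for i in range(16) for j in range(16) if i != j]
        for i, j in idx[:120]:
            w[i, j] = 0.9
        assert network_density(build_network(w, 0.1)) == pytest.approx(0.5)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            network_density(build_network(np.zeros((1, 1)), 0.1))


class TestGlobalEfficiency:
    def test_complete_equal_weight_graph_is_one(self):
        net = build_network(complete_matrix(5, 0.4), 0.1)
        assert global_efficiency(net) == pytest.approx(1.0)

    def test_empty_graph_is_zero_with_warning(self):
        net = build_network(np.zeros((4, 4)), 0.1)
        with pytest.warns(UserWarning, match="no suprathreshold"):
            assert global_efficiency(net) == 0.0

    def test_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            w = oracles.random_weight_matrix(rng, n)
            t = float(rng.uniform(0.2, 0.8))
            net = build_network(w, t)
            if net.n_edges == 0:
                continue
            assert global_efficiency(net) == pytest.approx(
                oracles.efficiency_bruteforce(net.weights, net.binary_adj), abs=1e-10
            )

    def test_matches_networkx_dijkstra(self):
        import networkx as nx

        rng = np.random.default_rng(6)
        w = oracles.random_weight_matrix(rng, 10)
        net = build_network(w, 0.5)
        w_max = net.weights[net.binary_adj].max()
        g = nx.DiGraph()
        g.add_nodes_from(range(10))
        for i in range(10):
            for j in range(10):
                if net.binary_adj[i, j]:  # edge j -> i
                    g.add_edge(j, i, length=w_max / net.weights[i, j])
        total = 0.0
        for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
            for dst, d in dists.items():
                if dst != src:
                    total += 1.0 / d
        assert global_efficiency(net) == pytest.approx(total / 90.0, abs=1e-10)


class TestMetricProperties:
    def test_scale_invariance_under_joint_weight_threshold_scaling(self):
        rng = np.random.default_rng(7)
        w = oracles.random_weight_matrix(rng, 8)
        t = 0.5
        m1 = network_metrics(w, t)
        m2 = network_metrics(0.01 * w, 0.01 * t)
        assert m1.C == pytest.approx(m2.C)
        assert m1.D == pytest.approx(m2.D)
        assert m1.E_global == pytest.approx(m2.E_global)

    def test_adding_an_edge_never_decreases_density_or_efficiency(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            w = oracles.random_weight_matrix(rng, 6)
            t = 0.6
            base = network_metrics(w, t)
            # promote one subthreshold entry above threshold
            sub = np.argwhere((w <= t) & ~np.eye(6, dtype=bool))
            above = w[w > t]
            if sub.size == 0 or above.size == 0:
                continue
            i, j = sub[rng.integers(len(sub))]
            w2 = w.copy()
            # keep the promoted edge below the current maximum so the
            # max-normalized lengths of existing edges are unchanged
            w2[i, j] = t + rng.uniform(0.1, 0.9) * (above.max() - t)
            grown = network_metrics(w2, t)
            assert grown.D >= base.D
            assert grown.E_global >= base.E_global - 1e-12

    def test_metrics_always_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            w = oracles.random_weight_matrix(rng, int(rng.integers(2, 10)))
            m = network_metrics(w, float(rng.uniform(0.0, 0.9)))
            assert 0.0 <= m.C <= 1.0
            assert 0.0 <= m.D <= 1.0
            assert 0.0 <= m.E_global <= 1.0
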