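import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from strokewc import (BinaryGraph, FCMatrix, ModulePartition,
                      consensus_modules, lesion_graph_metrics,
                      make_reference_signals, modularity, small_world,
                      static_fc, threshold_graph)


def _brute_clustering(adj):
    """Average clustering coefficient by explicit triangle counting."""
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs)
                    for b in nbrs[ai + 1:])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def _brute_path_length(adj):
    """Characteristic path length by BFS from every node."""
    n = adj.shape[0]
    total, count = 0, 0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if len(dist) < n:
            raise ValueError("disconnected")
        total += sum(d for node, d in dist.items() if node != s)
        count += n - 1
    return total / count


class TestThresholdGraph:
    def test_density_one_gives_complete_graph(self):
        fc = FCMatrix(np.random.default_rng(0).random((5, 5)))
        g = threshold_graph(fc, 1.0)
        assert g.n_edges == 10
        assert not np.diag(g.adjacency).any()

    def test_single_strongest_edge_survives(self):
        vals = np.zeros((4, 4))
        vals[1, 3] = vals[3, 1] = 0.9
        vals[0, 2] = vals[2, 0] = 0.2
        g = threshold_graph(FCMatrix(vals + np.eye(4)), 1.01 / 6)
        assert g.n_edges == 1 and g.adjacency[1, 3] == 1

    def test_tiny_density_gives_empty_graph(self):
        fc = FCMatrix(np.random.default_rng(1).random((6, 6)))
        g = threshold_graph(fc, 1e-6)
        assert g.n_edges == 0

    @pytest.mark.parametrize("density", [0.1, 0.25, 0.5, 0.8])
    def test_retained_edge_count(self, density):
        fc = FCMatrix(np.random.default_rng(2).random((12, 12)))
        g = threshold_graph(fc, density)
        assert g.n_edges == round(density * 66)

    def test_tie_break_is_deterministic(self):
        vals = np.ones((5, 5))
        a = threshold_graph(FCMatrix(vals), 0.3).adjacency
        b = threshold_graph(FCMatrix(vals.copy()), 0.3).adjacency
        assert (a == b).all()


class TestConsensusModules:
    def test_recovers_planted_blocks(self):
        bold, labels = make_reference_signals(24, 2400, 6, seed=3,
                                              within_corr=0.8)
        part = consensus_modules(static_fc(bold), k=6, runs=50, seed=0)
        assert adjusted_rand_score(labels, part.assignment) >= 0.9

    def test_deterministic_for_fixed_seed(self):
        bold, _ = make_reference_signals(12, 600, 3, seed=4)
        fc = static_fc(bold)
        a = consensus_modules(fc, k=3, runs=20, seed=5)
        b = consensus_modules(fc, k=3, runs=20, seed=5)
        assert (a.assignment == b.assignment).all()

    def test_k_equals_n_gives_singletons(self):
        bold, _ = make_reference_signals(6, 400, 2, seed=6)
        part = consensus_modules(static_fc(bold), k=6, runs=10, seed=0)
        assert len(set(part.assignment.tolist())) == 6

    def test_degenerate_fc_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            consensus_modules(np.ones((8, 8)), k=2)


class TestModularity:
    def _two_cliques(self):
        adj = np.zeros((8, 8), dtype=int)
        adj[:4, :4] = 1 - np.eye(4)
        adj[4:, 4:] = 1 - np.eye(4)
        return BinaryGraph(adj, density=12 / 28)

    def test_two_cliques_hand_value(self):
        g = self._two_cliques()
        p = ModulePartition([0] * 4 + [1] * 4, k=2)
        assert modularity(g, p) == pytest.approx(0.5)

    def test_single_module_always_zero(self):
        for seed in range(5):
            G = nx.gnm_random_graph(10, 20, seed=seed)
            g = BinaryGraph(nx.to_numpy_array(G).astype(int), 20 / 45)
            p = ModulePartition([0] * 10, k=1)
            assert modularity(g, p) == pytest.approx(0.0)

    def test_misaligned_partition_scores_lower(self):
        g = self._two_cliques()
        aligned = ModulePartition([0] * 4 + [1] * 4, k=2)
        split = ModulePartition([0, 0, 1, 1, 2, 2, 3, 3], k=4)
        assert modularity(g, split) < modularity(g, aligned)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnm_random_graph(10, 18, seed=seed)
        adj = nx.to_numpy_array(G).astype(int)
        assignment = rng.integers(0, 3, 10)
        communities = [set(np.flatnonzero(assignment == u))
                       for u in range(3)]
        communities = [c for c in communities if c]
        expected = nx.community.modularity(G, communities)
        got = modularity(BinaryGraph(adj, 18 / 45),
                         ModulePartition(assignment, k=3))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        g = self._two_cliques()
        for _ in range(5):
            p = ModulePartition(np.random.default_rng(1).integers(0, 3, 8), 3)
            assert -1.0 <= modularity(g, p) <= 1.0

    def test_edgeless_graph_rejected(self):
        g = BinaryGraph(np.zeros((4, 4), dtype=int), 0.0)
        with pytest.raises(ValueError, match="edgeless"):
            modularity(g, ModulePartition([0, 0, 1, 1], 2))


class TestSmallWorld:
    def test_complete_graph_scores_one(self):
        adj = (1 - np.eye(6)).astype(int)
        g = BinaryGraph(adj, 1.0)
        assert small_world(g, n_random=5, seed=0) == pytest.approx(1.0)

    def test_random_graph_scores_near_one(self):
        G = nx.gnm_random_graph(16, 48, seed=1)
        assert nx.is_connected(G)
        g = BinaryGraph(nx.to_numpy_array(G).astype(int), 48 / 120)
        assert small_world(g, n_random=50, seed=2) == pytest.approx(1.0,
                                                                    abs=0.3)

    def test_watts_strogatz_regime_exceeds_one(self):
        G = nx.connected_watts_strogatz_graph(20, 6, 0.1, seed=3)
        g = BinaryGraph(nx.to_numpy_array(G).astype(int),
                        G.number_of_edges() / 190)
        assert small_world(g, n_random=50, seed=4) > 1.0

    def test_disconnected_graph_rejected(self):
        adj = np.zeros((6, 6), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(ValueError, match="connected"):
            small_world(BinaryGraph(adj, 1 / 15))

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_brute_force(self, seed):
        G = nx.gnm_random_graph(10, 22, seed=seed)
        if not nx.is_connected(G):
            pytest.skip("sampled graph disconnected")
        adj = nx.to_numpy_array(G).astype(int)
        assert nx.average_clustering(G) == pytest.approx(
            _brute_clustering(adj), abs=1e-12)
        assert nx.average_shortest_path_length(G) == pytest.approx(
            _brute_path_length(adj), abs=1e-12)


class TestLesionGraphMetrics:
    def _modular_fc(self, decorrelate_hub=False, seed=7):
        bold, labels = make_reference_signals(16, 1500, 4, seed=seed,
                                              within_corr=0.7)
        series = bold.series.copy()
        if decorrelate_hub:
            rng = np.random.default_rng(seed + 1)
            series[0] = rng.standard_normal(series.shape[1])
        return static_fc(series), labels

    def test_lesioned_node_removed_before_metrics(self):
        fc, labels = self._modular_fc()
        part = ModulePartition(labels, k=4)
        out = lesion_graph_metrics(fc, 3, part, n_random=5, seed=0)
        assert len(out["Q"]) == len(out["q_densities"])
        assert np.isfinite(out["Q_mean"])

    def test_decorrelated_hub_lowers_modularity(self):
        fc0, labels = self._modular_fc(decorrelate_hub=False)
        fc1, _ = self._modular_fc(decorrelate_hub=True)
        part = ModulePartition(labels, k=4)
        base = lesion_graph_metrics(fc0, None, part, n_random=5, seed=0)
        hub = lesion_graph_metrics(fc1, None, part, n_random=5, seed=0)
        assert hub["Q_mean"] < base["Q_mean"]

    def test_self_comparison_is_unity(self):
        fc, labels = self._modular_fc()
        part = ModulePartition(labels, k=4)
        a = lesion_graph_metrics(fc, None, part, n_random=5, seed=1)
        b = lesion_graph_metrics(fc, None, part, n_random=5, seed=1)
        np.testing.assert_allclose(a["Q"] / b["Q"], 1.0)
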