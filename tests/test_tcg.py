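"""Temporal causal graph: lagged weights, thresholding, graph features."""

import numpy as np
import pytest

from fedcep.errors import ArgumentError, DataError
from fedcep.synthetic import PanelSpec, generate_panel
from fedcep.tcg import (TCG_FEATURE_NAMES, build_node_matrix, build_tcg,
                        extract_tcg_features, lagged_edge_weight)


class TestLaggedEdgeWeight:
    def test_zero_series_gives_zero(self):
        z = np.zeros(50)
        assert lagged_edge_weight(z, z, 1) == 0.0

    def test_unstandardized_constant_ones(self):
        ones = np.ones(5)
        w = lagged_edge_weight(ones, ones, 1, standardize_first=False)
        assert w == pytest.approx(4 / 4)

    def test_delayed_copy_has_weight_near_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        a = (a - a.mean()) / a.std(ddof=1)
        b = np.roll(a, 1)
        w = lagged_edge_weight(a, b, 1)
        assert 0.95 <= w <= 1.0

    def test_lag_out_of_range(self):
        with pytest.raises(ArgumentError):
            lagged_edge_weight(np.ones(5), np.ones(5), 5)


class TestBuildTCG:
    def test_null_panel_yields_sparse_adjacency(self):
        panel, _ = generate_panel(PanelSpec(6, 500, 1, [], 1.0, seed=13))
        g = build_tcg(panel, max_lag=3, threshold=0.3)
        frac = np.count_nonzero(g.adjacency) / (6 * 6)
        assert frac <= 0.05

    def test_planted_edge_dominates(self):
        panel, _ = generate_panel(PanelSpec(4, 500, 1, [(0, 2, 0.9)], 0.1, seed=7))
        g = build_tcg(panel, max_lag=3, threshold=0.3)
        assert g.adjacency[2, 0] != 0.0
        assert abs(g.adjacency[2, 0]) == np.abs(g.adjacency).max()

    def test_subthreshold_weight_gives_zero_entry(self):
        # two independent noise series: raw correlation far below 0.3
        rng = np.random.default_rng(1)
        panel = rng.normal(size=(400, 2))
        g = build_tcg(panel, max_lag=1, threshold=0.3)
        assert np.count_nonzero(g.adjacency) == 0

    def test_normalized_weights_bounded_with_extremum_one(self):
        panel, _ = generate_panel(PanelSpec(5, 300, 1, [(0, 1, 0.8)], 0.2, seed=3))
        g = build_tcg(panel, max_lag=3, threshold=0.3)
        norms = [abs(w) for (_, _, w) in g.best_edges.values()]
        assert max(norms) == pytest.approx(1.0)
        assert all(v <= 1.0 + 1e-12 for v in norms)

    def test_raising_threshold_never_adds_edges(self):
        panel, _ = generate_panel(PanelSpec(5, 300, 1, [(0, 1, 0.6), (2, 3, 0.5)], 0.3, seed=9))
        counts = [np.count_nonzero(build_tcg(panel, threshold=t).adjacency)
                  for t in (0.1, 0.3, 0.5, 0.7)]
        assert counts == sorted(counts, reverse=True)

    def test_too_few_steps_is_data_error(self):
        with pytest.raises(DataError):
            build_tcg(np.zeros((4, 3)), max_lag=3)

    def test_recovery_auc_small_sample(self):
        # quick 3-seed sanity; the full 20-seed check lives in the acceptance suite
        assert planted_edge_auc(range(3)) >= 0.9


def planted_edge_auc(seeds, n_nodes=6, coeff=0.8, noise=0.2, n_steps=300):
    """Rank ordered node pairs by |normalized weight| against ground truth."""
    from sklearn.metrics import roc_auc_score

    planted = [(0, 3, coeff), (1, 4, coeff), (2, 5, coeff), (0, 4, coeff)]
    truth, scores = [], []
    for seed in seeds:
        panel, _ = generate_panel(PanelSpec(n_nodes, n_steps, 1, planted, noise, seed=seed))
        g = build_tcg(panel, max_lag=3, threshold=0.3)
        planted_pairs = {(s, t) for s, t, _ in planted}
        for (s, t), (_, _, w) in g.best_edges.items():
            truth.append((s, t) in planted_pairs)
            scores.append(abs(w))
    return roc_auc_score(truth, scores)


class TestExtractFeatures:
    def _graph_from_adjacency(self, A):
        from fedcep.tcg import TemporalCausalGraph

        n = len(A)
        best = {}
        for s in range(n):
            for t in range(n):
                if s != t:
                    best[(s, t)] = (1, A[t][s], A[t][s])
        return TemporalCausalGraph([f"n{i}" for i in range(n)], 1, 0.3, best,
                                   np.asarray(A, dtype=float))

    def test_chain_degrees_and_length(self):
        # a -> b -> c
        A = [[0, 0, 0], [0.8, 0, 0], [0, 0.7, 0]]
        feats = extract_tcg_features(self._graph_from_adjacency(A))
        names = list(TCG_FEATURE_NAMES)
        c = feats[2]
        assert c[names.index("in_degree")] == 1
        assert c[names.index("out_degree")] == 0
        assert feats[0][names.index("chain_length")] == 2

    def test_empty_adjacency_gives_zero_features_and_singleton_sccs(self):
        feats = extract_tcg_features(self._graph_from_adjacency(np.zeros((4, 4))))
        names = list(TCG_FEATURE_NAMES)
        assert (feats[:, names.index("scc_size")] == 1).all()
        mask = np.ones(len(names), dtype=bool)
        mask[names.index("scc_size")] = False
        assert (feats[:, mask] == 0).all()

    def test_weighted_degree_is_absolute_sum(self):
        A = [[0, 0.5, -0.4], [0, 0, 0], [0, 0, 0]]  # node 0 receives 0.5 and -0.4
        feats = extract_tcg_features(self._graph_from_adjacency(A))
        assert feats[0][list(TCG_FEATURE_NAMES).index("weighted_degree")] == pytest.approx(0.9)

    def test_cycle_chain_length_counts_scc(self):
        # a <-> b cycle plus c downstream
        A = [[0, 0.5, 0], [0.5, 0, 0], [0.4, 0, 0]]
        feats = extract_tcg_features(self._graph_from_adjacency(A))
        names = list(TCG_FEATURE_NAMES)
        assert feats[0][names.index("scc_size")] == 2
        assert feats[0][names.index("chain_length")] == 2  # within SCC (1) + step to c


class TestNodeMatrix:
    def test_column_count_is_concatenation(self, rng):
        F = rng.random((20, 11))
        N = rng.random((11, 8))
        assert build_node_matrix(F, N).shape == (20, 19)

    def test_zero_tcg_features_pads_with_zeros(self, rng):
        F = rng.random((10, 4))
        K = build_node_matrix(F, np.zeros((4, 9)))
        np.testing.assert_array_equal(K[:, :4], F)
        np.testing.assert_array_equal(K[:, 4:], 0.0)

    def test_deterministic(self, rng):
        F = rng.random((10, 4))
        N = rng.random((4, 9))
        np.testing.assert_array_equal(build_node_matrix(F, N), build_node_matrix(F, N))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(DataError):
            build_node_matrix(rng.random((5, 3)), rng.random((4, 9)))
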