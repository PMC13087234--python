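"""MCN-GNN: graph construction, centering, forward/backward, local training."""

import numpy as np
import pytest

from fedcep.errors import ArgumentError, DataError
from fedcep.gnn import (GNNClassifier, GNNParams, TrainConfig, build_ehr_graph,
                        gnn_forward, mcn)


class TestBuildEHRGraph:
    def test_k_zero_gives_identity(self, rng):
        A = build_ehr_graph(rng.random((6, 3)), 0)
        np.testing.assert_array_equal(A, np.eye(6))

    def test_identical_rows_are_mutual_neighbours(self, rng):
        K = rng.random((5, 4))
        K[3] = K[1]
        A = build_ehr_graph(K, 1)
        assert A[1, 3] == 1.0 and A[3, 1] == 1.0

    def test_degrees_bounded_after_symmetrization(self, rng):
        A = build_ehr_graph(rng.random((5, 3)), 2)
        degrees = A.sum(axis=1) - 1  # exclude self-loop
        assert ((degrees >= 2) & (degrees <= 4)).all()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ArgumentError):
            build_ehr_graph(rng.random((4, 2)), 4)


class TestMCN:
    def test_hand_example(self):
        out = mcn(np.array([[1.0, 3.0], [3.0, 5.0]]))
        np.testing.assert_array_equal(out, [[-1.0, -1.0], [1.0, 1.0]])

    def test_column_means_vanish(self, rng):
        out = mcn(rng.normal(size=(40, 7)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_single_node_maps_to_zero(self):
        np.testing.assert_array_equal(mcn(np.array([[2.0, -4.0]])), [[0.0, 0.0]])


def _identity_params(n_layers=1):
    """1-dim network with identity weights and zero biases."""
    eye = np.array([[1.0]])
    z = np.zeros(1)
    return GNNParams(embed=(eye.copy(), z.copy()),
                     layers=[(eye.copy(), z.copy()) for _ in range(n_layers)],
                     readout=(eye.copy(), z.copy()),
                     head=(np.array([[1.0, -1.0]]), np.zeros(2)))


class TestForward:
    def test_zero_parameters_give_uniform_probabilities(self, rng):
        X = rng.random((6, 3))
        params = GNNParams.init(3, 4, 2, rng)
        zero = params.unflatten_like(np.zeros(params.n_parameters))
        probs = gnn_forward(build_ehr_graph(X, 2), X, zero)
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        X = rng.random((10, 5))
        params = GNNParams.init(5, 8, 3, rng)
        probs = gnn_forward(build_ehr_graph(X, 3), X, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_hand_message_on_two_node_graph(self):
        # features [1], [3]; full graph with self-loops; identity weights:
        # mean aggregation gives [2], [2] before MCN
        X = np.array([[1.0], [3.0]])
        A = np.ones((2, 2))
        params = _identity_params()
        _, cache = gnn_forward(A, X, params, return_cache=True)
        np.testing.assert_allclose(cache["agg"][0], [[2.0], [2.0]])

    def test_mcn_applied_after_every_layer(self, rng):
        X = rng.random((12, 4))
        params = GNNParams.init(4, 6, 4, rng)
        _, cache = gnn_forward(build_ehr_graph(X, 3), X, params, return_cache=True)
        for H in cache["H"][1:]:
            np.testing.assert_allclose(H.mean(axis=0), 0.0, atol=1e-10)

    def test_mcn_preserves_node_distinctness_versus_plain_stack(self, rng):
        # after 4 rounds of averaging, centering keeps the nodes more
        # distinguishable (mean pairwise distance of unit-norm features)
        # than the same stack without it: the uncentred stack accumulates a
        # shared positive drift through the ReLU residuals
        X = rng.normal(size=(30, 5))
        params = GNNParams.init(5, 16, 4, rng)
        A = build_ehr_graph(X, 5)
        P = A / A.sum(axis=1, keepdims=True)

        def run(with_mcn):
            W0, b0 = params.embed
            H = X @ W0 + b0
            for W, b in params.layers:
                M = np.maximum(P @ H @ W + b, 0.0)
                H = H + M
                if with_mcn:
                    H = mcn(H)
            U = H / np.linalg.norm(H, axis=1, keepdims=True)
            diff = U[:, None, :] - U[None, :, :]
            return (diff ** 2).sum(axis=-1).mean()

        assert run(True) >= run(False)


class TestTraining:
    def _separable(self, n=500, seed=1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        K = np.hstack([X, 0.1 * rng.normal(size=(n, 3))])
        return K, y

    def test_separable_cohort_reaches_high_train_accuracy(self):
        K, y = self._separable()
        res = GNNClassifier(K, y, TrainConfig(epochs=50, seed=1)).fit()
        assert res.train_accuracy >= 0.95

    def test_seeded_determinism_of_round_gradient(self):
        K, y = self._separable(n=120)
        cfg = TrainConfig(epochs=3, seed=4)
        r1 = GNNClassifier(K, y, cfg).fit()
        r2 = GNNClassifier(K, y, cfg).fit()
        np.testing.assert_array_equal(r1.gradient, r2.gradient)

    def test_gradient_length_equals_parameter_count(self):
        K, y = self._separable(n=80)
        model = GNNClassifier(K, y, TrainConfig(epochs=2, seed=0))
        res = model.fit()
        assert len(res.gradient) == res.params.n_parameters

    def test_loss_decreases_over_first_epochs(self):
        # non-strict, averaged over 5 seeds
        drops = []
        for seed in range(5):
            K, y = self._separable(n=300, seed=seed)
            res = GNNClassifier(K, y, TrainConfig(epochs=10, seed=seed)).fit()
            drops.append(res.loss_history[0] - res.loss_history[-1])
        assert np.mean(drops) > 0

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(DataError):
            GNNClassifier(rng.random((30, 3)), np.zeros(30, dtype=int),
                          TrainConfig(epochs=1))

    def test_80_20_split_counts(self):
        K, y = self._separable(n=219)
        res = GNNClassifier(K, y, TrainConfig(epochs=1, seed=0)).fit()
        assert res.n_train == int(np.floor(0.8 * 219))
        assert res.n_test == 219 - res.n_train

    def test_summary_mentions_architecture(self):
        K, y = self._separable(n=100)
        res = GNNClassifier(K, y, TrainConfig(epochs=2, seed=0)).fit()
        text = res.summary()
        assert "train accuracy" in text and "layers: 3" in text

    def test_flatten_unflatten_round_trip(self, rng):
        params = GNNParams.init(7, 8, 3, rng)
        again = params.unflatten_like(params.flatten())
        np.testing.assert_array_equal(params.flatten(), again.flatten())
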