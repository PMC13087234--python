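"""Evaluation metrics against independent literal-loop oracles."""

import math

import numpy as np
import pytest

from fedcep.errors import ArgumentError
from fedcep.metrics import (ConfusionCounts, attack_level, classification_metrics,
                            cluster_quality, continual_metrics, davies_bouldin,
                            jain_index, loss_convergence_rate, mae, mse,
                            security_level, silhouette)

# ---------------------------------------------------------------------------
# literal-loop oracles, written independently of the implementation


def _oracle_continual(alpha, Tn):
    retained = 0.0
    for s in range(1, Tn):
        retained += alpha[Tn][s]
    retained /= Tn - 1
    forgetting = 0.0
    for s in range(1, Tn):
        best = max(alpha[v][s] for v in range(s))
        forgetting += best - alpha[Tn][s]
    forgetting /= Tn - 1
    forward = 0.0
    for s in range(2, Tn):
        forward += alpha[s - 1][s] - alpha[0][s]
    forward /= Tn - 1
    backward = 0.0
    for s in range(1, Tn):
        backward += alpha[Tn][s] - alpha[s][s]
    backward /= Tn - 1
    return retained, forgetting, forward, backward


def _oracle_silhouette(points, labels):
    n = len(points)
    total = 0.0
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        intra = sum(math.dist(points[i], points[j]) for j in own) / len(own)
        near = math.inf
        for lab in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == lab]
            near = min(near, sum(math.dist(points[i], points[j]) for j in members) / len(members))
        total += (near - intra) / max(intra, near)
    return total / n


def _oracle_dbi(points, labels):
    labs = sorted(set(labels))
    cents, spreads = [], []
    for lab in labs:
        members = [points[j] for j in range(len(points)) if labels[j] == lab]
        c = [sum(col) / len(members) for col in zip(*members)]
        cents.append(c)
        spreads.append(sum(math.dist(m, c) for m in members) / len(members))
    total = 0.0
    for b in range(len(labs)):
        worst = -math.inf
        for c in range(len(labs)):
            if b == c:
                continue
            worst = max(worst, (spreads[b] + spreads[c]) / math.dist(cents[b], cents[c]))
        total += worst
    return total / len(labs)


class TestContinualMetrics:
    def test_constant_perfect_matrix(self):
        alpha = np.ones((5, 5))
        out = continual_metrics(alpha, 4)
        assert out["retained_accuracy"] == 1.0
        assert out["average_forgetting"] == 0.0
        assert out["backward_transfer"] == 0.0

    def test_retained_accuracy_hand_example(self):
        alpha = np.zeros((4, 4))
        alpha[3, 1], alpha[3, 2] = 0.8, 0.9
        assert continual_metrics(alpha, 3)["retained_accuracy"] == pytest.approx(0.85)

    def test_matches_literal_loop_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            Tn = int(rng.integers(2, 6))
            alpha = rng.random((Tn + 1, Tn + 1))
            got = continual_metrics(alpha, Tn)
            r, f, fw, bw = _oracle_continual(alpha.tolist(), Tn)
            assert got["retained_accuracy"] == pytest.approx(r, abs=1e-12)
            assert got["average_forgetting"] == pytest.approx(f, abs=1e-12)
            assert got["forward_transfer"] == pytest.approx(fw, abs=1e-12)
            assert got["backward_transfer"] == pytest.approx(bw, abs=1e-12)

    def test_forgetting_nonnegative_on_degrading_runs(self, rng):
        # every column's accuracy degrades monotonically over training rows,
        # so the final row never exceeds any earlier row
        for _ in range(20):
            Tn = 4
            alpha = np.zeros((Tn + 1, Tn + 1))
            for s in range(1, Tn + 1):
                start = rng.uniform(0.7, 1.0)
                for v in range(Tn + 1):
                    alpha[v, s] = start - rng.uniform(0.0, 0.1) * v
            assert continual_metrics(alpha, Tn)["average_forgetting"] >= -1e-12

    def test_single_task_rejected(self):
        with pytest.raises(ArgumentError):
            continual_metrics(np.ones((2, 2)), 1)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        out = classification_metrics(ConfusionCounts(1, 1, 0, 0))
        assert (out["accuracy"], out["precision"], out["recall"], out["f_measure"]) == (1, 1, 1, 1)

    def test_hand_arithmetic(self):
        out = classification_metrics(ConfusionCounts(TP=8, TN=8, FP=2, FN=2))
        for key in ("accuracy", "precision", "recall", "f_measure"):
            assert out[key] == pytest.approx(0.8)

    def test_zero_denominator_yields_undefined_marker(self):
        out = classification_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(out["precision"])

    def test_matches_literal_loops_on_random_counts(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, size=4))
            out = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert out["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            assert out["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert out["recall"] == pytest.approx(tp / (tp + fn), abs=1e-12)
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert out["f_measure"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)
            assert out["npv"] == pytest.approx(tn / (tn + fn), abs=1e-12)
            assert out["fnr"] == pytest.approx(fn / (fn + tp), abs=1e-12)
            assert out["fpr"] == pytest.approx(fp / (fp + tn), abs=1e-12)


class TestRegressionAndFairness:
    def test_identity_predictions(self, rng):
        x = rng.random(20)
        assert mse(x, x) == 0.0 and mae(x, x) == 0.0

    def test_mse_mae_match_loops(self, rng):
        for _ in range(50):
            p, a = rng.random(10), rng.random(10)
            assert mse(p, a) == pytest.approx(sum((ai - pi) ** 2 for pi, ai in zip(p, a)) / 10, abs=1e-12)
            assert mae(p, a) == pytest.approx(sum(abs(ai - pi) for pi, ai in zip(p, a)) / 10, abs=1e-12)

    def test_jain_closed_forms(self):
        assert jain_index(np.full(7, 3.0)) == pytest.approx(1.0)
        assert jain_index(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(0.25)

    def test_jain_bounds_property(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 20))
            x = rng.random(n) + 1e-9
            j = jain_index(x)
            assert 1 / n - 1e-12 <= j <= 1 + 1e-12

    def test_loss_convergence_rate(self):
        assert loss_convergence_rate(1.0, 0.4, 0, 10) == pytest.approx(-0.06)
        with pytest.raises(ArgumentError):
            loss_convergence_rate(1.0, 0.4, 3, 3)


class TestClusterQuality:
    def test_tight_far_clusters_have_high_silhouette(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, size=(20, 2)),
                         rng.normal(10, 0.01, size=(20, 2))])
        labels = np.array([0] * 20 + [1] * 20)
        assert silhouette(pts, labels) >= 0.99

    def test_dbi_hand_example(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        assert davies_bouldin(pts, labels) == pytest.approx(0.01)

    def test_coincident_clusters_give_infinite_dbi(self):
        pts = np.zeros((4, 2))
        assert davies_bouldin(pts, np.array([0, 0, 1, 1])) == float("inf")

    def test_matches_literal_loop_oracles(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(15, 3))
            labels = rng.integers(0, 3, size=15)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette(pts, labels) == pytest.approx(
                _oracle_silhouette(pts.tolist(), labels.tolist()), abs=1e-12)
            assert davies_bouldin(pts, labels) == pytest.approx(
                _oracle_dbi(pts.tolist(), labels.tolist()), abs=1e-12)

    def test_agrees_with_sklearn_on_generic_instances(self, rng):
        from sklearn.metrics import davies_bouldin_score, silhouette_score

        pts = rng.normal(size=(40, 4))
        labels = rng.integers(0, 3, size=40)
        out = cluster_quality(pts, labels)
        assert out["silhouette"] == pytest.approx(silhouette_score(pts, labels), abs=1e-9)
        assert out["davies_bouldin"] == pytest.approx(davies_bouldin_score(pts, labels), abs=1e-9)


class TestSecurityMetrics:
    def test_all_components_perfect(self):
        assert security_level(np.full(5, 100.0)) == pytest.approx(100.0)

    def test_equal_weights_mean(self):
        assert security_level(np.full(5, 90.0), np.full(5, 0.2)) == pytest.approx(90.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ArgumentError):
            security_level(np.full(5, 50.0), np.full(5, 0.3))

    def test_attack_level(self):
        assert attack_level(0, 50) == 0.0
        assert attack_level(5, 50) == pytest.approx(0.1)
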