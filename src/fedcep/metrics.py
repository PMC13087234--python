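"""Evaluation metrics as pure functions.

Continual-learning metrics operate on the task-accuracy matrix alpha[v, s]
(accuracy on task s after learning task v, 1-based; row 0 is the accuracy of
the randomly initialized model, needed by forward transfer). Classification
ratios come from confusion counts; a zero denominator yields the sentinel
``UNDEFINED`` rather than 0. Cluster validity (silhouette, Davies-Bouldin)
and fairness (Jain's index) follow their textbook definitions with explicit
degenerate-case conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError

#: sentinel for a metric whose denominator is zero
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ArgumentError("confusion counts must be nonnegative")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F-measure, PPV, NPV, FNR, FPR."""
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    return {
        "accuracy": _ratio(c.TP + c.TN, c.TP + c.TN + c.FP + c.FN),
        "precision": precision,
        "recall": recall,
        "f_measure": (2 * precision * recall / (precision + recall)
                      if not (math.isnan(precision) or math.isnan(recall))
                      and (precision + recall) > 0 else UNDEFINED),
        "ppv": precision,
        "npv": _ratio(c.TN, c.TN + c.FN),
        "fnr": _ratio(c.FN, c.FN + c.TP),
        "fpr": _ratio(c.FP, c.FP + c.TN),
    }


def continual_metrics(alpha: np.ndarray, Tn: int) -> dict[str, float]:
    """Retained accuracy, average forgetting, forward and backward transfer.

    ``alpha`` is (Tn+1) x (Tn+1): row v (1..Tn) holds accuracies after
    learning task v, row 0 the pre-training accuracies; column s (1..Tn)
    indexes the evaluated task. Forward transfer sums s = 2..Tn-1 as printed
    (the last task is skipped).
    """
    alpha = np.asarray(alpha, dtype=float)
    if Tn < 2:
        raise ArgumentError("need at least two tasks")
    if alpha.shape[0] < Tn + 1 or alpha.shape[1] < Tn + 1:
        raise ArgumentError(f"alpha must be at least {(Tn + 1, Tn + 1)}, got {alpha.shape}")
    retained = sum(alpha[Tn, s] for s in range(1, Tn)) / (Tn - 1)
    # max_{v < s} ranges over all earlier rows including the pre-training row 0
    forgetting = sum(max(alpha[v, s] for v in range(0, s)) - alpha[Tn, s]
                     for s in range(1, Tn)) / (Tn - 1)
    forward = sum(alpha[s - 1, s] - alpha[0, s] for s in range(2, Tn)) / (Tn - 1)
    backward = sum(alpha[Tn, s] - alpha[s, s] for s in range(1, Tn)) / (Tn - 1)
    return {"retained_accuracy": retained, "average_forgetting": forgetting,
            "forward_transfer": forward, "backward_transfer": backward}


def mse(predictions: np.ndarray, actuals: np.ndarray) -> float:
    p, a = np.asarray(predictions, float), np.asarray(actuals, float)
    if p.shape != a.shape:
        raise ArgumentError("length mismatch")
    return float(np.mean((a - p) ** 2))


def mae(predictions: np.ndarray, actuals: np.ndarray) -> float:
    p, a = np.asarray(predictions, float), np.asarray(actuals, float)
    if p.shape != a.shape:
        raise ArgumentError("length mismatch")
    return float(np.mean(np.abs(a - p)))


def jain_index(allocations: np.ndarray) -> float:
    """(sum x)^2 / (n * sum x^2); 1 for equal shares, 1/n for one-hot."""
    x = np.asarray(allocations, dtype=float)
    if x.size == 0 or (x < 0).any() or not x.any():
        raise ArgumentError("allocations must be nonnegative and not all zero")
    return float(x.sum() ** 2 / (x.size * np.sum(x ** 2)))


def loss_convergence_rate(loss_start: float, loss_end: float,
                          round_start: int, round_end: int) -> float:
    if round_end == round_start:
        raise ArgumentError("round_end must differ from round_start")
    return (loss_end - loss_start) / (round_end - round_start)


def silhouette(points: np.ndarray, assignment: np.ndarray) -> float:
    """Mean over points of (Near - Int)/max(Int, Near), Euclidean metric.

    Int is the mean distance to the point's own cluster (excluding itself),
    Near the smallest mean distance to another cluster; a singleton cluster
    contributes 0.
    """
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ArgumentError("need at least two clusters")
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=2))
    scores = np.zeros(len(points))
    for i in range(len(points)):
        own = assignment == assignment[i]
        if own.sum() == 1:
            continue  # singleton convention: 0
        intra = dist[i, own].sum() / (own.sum() - 1)
        near = min(dist[i, assignment == lab].mean()
                   for lab in labels if lab != assignment[i])
        scores[i] = (near - intra) / max(intra, near)
    return float(scores.mean())


def davies_bouldin(points: np.ndarray, assignment: np.ndarray) -> float:
    """(1/nC) sum_b max_{c != b} (Cu_b + Cu_c)/Sp_bc; +inf when any needed
    centroid separation is zero."""
    points = np.asarray(points, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ArgumentError("need at least two clusters")
    centroids = np.array([points[assignment == lab].mean(axis=0) for lab in labels])
    spread = np.array([np.mean(np.linalg.norm(points[assignment == lab] - centroids[k], axis=1))
                       for k, lab in enumerate(labels)])
    total = 0.0
    for b in range(len(labels)):
        worst = -np.inf
        for c in range(len(labels)):
            if c == b:
                continue
            sep = float(np.linalg.norm(centroids[b] - centroids[c]))
            ratio = (spread[b] + spread[c]) / sep if sep > 0 else float("inf")
            worst = max(worst, ratio)
        total += worst
    return float(total / len(labels))


def cluster_quality(points: np.ndarray, assignment: np.ndarray) -> dict[str, float]:
    return {"silhouette": silhouette(points, assignment),
            "davies_bouldin": davies_bouldin(points, assignment)}


def security_level(contributions: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted mean of the five security component percentages."""
    c = np.asarray(contributions, dtype=float)
    w = np.full(c.size, 1.0 / c.size) if weights is None else np.asarray(weights, float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ArgumentError(f"weights must sum to 1, got {w.sum()}")
    if ((c < 0) | (c > 100)).any():
        raise ArgumentError("contributions must lie in [0, 100]")
    return float(np.dot(w, c))


def attack_level(successful: int, total: int) -> float:
    if total <= 0:
        raise ArgumentError("total attacks must be positive")
    return successful / total
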