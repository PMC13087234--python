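"""Cluster-wise gradient aggregation (CHI-initialized k-means with the
Zhonghua distance).

Candidate centroid sets are sampled from the gradient collection and scored
with the Calinski-Harabasz index (CHI) after one assignment pass; the best-
scoring set seeds a Lloyd loop in which points are assigned by the Zhonghua
distance — a Huber-penalized weighted deviation magnitude modulated by a
cosine-similarity factor. Empty clusters are repaired by seizing the point
farthest from its centroid; each final cluster's aggregate is the mean of
its member gradients.

The literal similarity factor is (1 + cosine), which rewards similar vectors
with a *larger* distance; it is kept as the default for fidelity, with
"minus" ((1 - cosine)) and "off" (factor 1) variants available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError

MAX_LLOYD_ITERATIONS = 100


@dataclass
class ZDConfig:
    """Zhonghua-distance parameters: feature weights, Huber width, factor sign."""

    feature_weights: np.ndarray | float = 1.0
    huber_delta: float = 1.0
    similarity: str = "plus"  # "plus" (literal), "minus", or "off"

    def validate(self) -> None:
        if self.huber_delta <= 0:
            raise ArgumentError("huber_delta must be > 0")
        if self.similarity not in ("plus", "minus", "off"):
            raise ArgumentError("similarity must be 'plus', 'minus' or 'off'")
        if isinstance(self.feature_weights, np.ndarray) and (self.feature_weights < 0).any():
            raise ArgumentError("feature weights must be nonnegative")


def chi_score(points: np.ndarray, centroids: np.ndarray, assignment: np.ndarray) -> float:
    """Calinski-Harabasz index (eta1/eta2) * ((n - p)/(p - 1)).

    eta1 is the between-cluster dispersion sum_k n_k ||mu_k - mu||^2, eta2
    the within-cluster dispersion; eta2 = 0 returns +inf, eta1 = 0 returns 0.
    Cluster means are recomputed from the assignment (empty clusters keep the
    supplied centroid and contribute nothing).
    """
    points = np.asarray(points, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    n, p = len(points), len(centroids)
    if p < 2 or n <= p:
        raise ArgumentError(f"need n > p >= 2, got n={n}, p={p}")
    mu = points.mean(axis=0)
    eta1 = eta2 = 0.0
    for k in range(p):
        members = points[assignment == k]
        if len(members) == 0:
            continue
        mu_k = members.mean(axis=0)
        eta1 += len(members) * float(np.sum((mu_k - mu) ** 2))
        eta2 += float(np.sum((members - mu_k) ** 2))
    if eta2 == 0.0:
        return float("inf") if eta1 > 0.0 else 0.0
    return (eta1 / eta2) * ((n - p) / (p - 1))


def _huber(t: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(t)
    return np.where(a <= delta, 0.5 * t * t, delta * (a - 0.5 * delta))


def zhonghua_distance(L: np.ndarray, x: np.ndarray, config: ZDConfig | None = None) -> float:
    """sqrt(sum r * huber(L - x)) * similarity factor.

    The factor is (1 + cos), (1 - cos) or 1 by config; a zero vector makes
    the cosine term 0 by convention.
    """
    config = config or ZDConfig()
    config.validate()
    L = np.asarray(L, dtype=float)
    x = np.asarray(x, dtype=float)
    if L.shape != x.shape:
        raise DataError("vector length mismatch in zhonghua_distance")
    r = config.feature_weights
    core = float(np.sqrt(np.sum(r * _huber(L - x, config.huber_delta))))
    if config.similarity == "off":
        return core
    nl, nx = np.linalg.norm(L), np.linalg.norm(x)
    cos = float(L @ x / (nl * nx)) if nl > 0 and nx > 0 else 0.0
    factor = 1.0 + cos if config.similarity == "plus" else 1.0 - cos
    return core * factor


def _distances(points: np.ndarray, centroids: np.ndarray, config: ZDConfig) -> np.ndarray:
    out = np.empty((len(points), len(centroids)))
    for k, c in enumerate(centroids):
        for i, x in enumerate(points):
            out[i, k] = zhonghua_distance(c, x, config)
    return out


@dataclass
class ClusterAssignment:
    """Final clustering of hospital gradients with per-cluster aggregates."""

    centroids: np.ndarray
    assignment: np.ndarray  # point index -> cluster index
    aggregates: np.ndarray  # X_k = mean of member gradients
    chi: float
    iterations: int
    hospital_ids: list[str] = field(default_factory=list)
    candidate_chis: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def to_json_dict(self) -> dict:
        return {"centroids": self.centroids.tolist(),
                "assignment": self.assignment.tolist(),
                "aggregates": self.aggregates.tolist(),
                "chi": self.chi, "iterations": self.iterations,
                "hospital_ids": self.hospital_ids}


def _assign(points, centroids, config):
    return _distances(points, centroids, config).argmin(axis=1)


def _repair_empty(points, centroids, assignment):
    """Give every empty cluster the point farthest from its current centroid."""
    p = len(centroids)
    for k in range(p):
        if np.any(assignment == k):
            continue
        dist = np.linalg.norm(points - centroids[assignment], axis=1)
        # only donate from clusters that can spare a point
        counts = np.bincount(assignment, minlength=p)
        dist[counts[assignment] <= 1] = -np.inf
        assignment[int(np.argmax(dist))] = k
    return assignment


def cluster_aggregate(gradients: np.ndarray, p: int, config: ZDConfig | None = None,
                      n_candidates: int = 10, seed: int = 0,
                      hospital_ids: list[str] | None = None,
                      initial_centroids: np.ndarray | None = None) -> ClusterAssignment:
    """CHI-initialized Zhonghua-distance k-means over gradient vectors.

    With fewer than 2 gradients or p = 1 the whole set forms one cluster
    whose aggregate is the plain mean. ``initial_centroids`` bypasses the
    CHI candidate search (used by equivalence tests).
    """
    G = np.atleast_2d(np.asarray(gradients, dtype=float))
    config = config or ZDConfig()
    config.validate()
    n = len(G)
    ids = hospital_ids or [f"h{i}" for i in range(n)]
    if len(ids) != n:
        raise DataError("hospital_ids length mismatch")

    if n < 2 or p == 1:
        agg = G.mean(axis=0, keepdims=True)
        return ClusterAssignment(agg.copy(), np.zeros(n, dtype=int), agg,
                                 float("nan"), 0, ids)
    if p < 1 or p > n:
        raise ArgumentError(f"need 1 <= p <= number of gradients, got p={p}, n={n}")

    rng = np.random.default_rng(seed)
    candidate_chis: list[float] = []
    if initial_centroids is not None:
        centroids = np.asarray(initial_centroids, dtype=float).copy()
        if centroids.shape != (p, G.shape[1]):
            raise DataError("initial_centroids shape mismatch")
    else:
        best, best_chi = None, -np.inf
        for _ in range(n_candidates):
            cand = G[rng.choice(n, size=p, replace=False)].copy()
            a = _assign(G, cand, config)
            score = chi_score(G, cand, a) if n > p else 0.0
            candidate_chis.append(score)
            if score > best_chi:
                best, best_chi = cand, score
        centroids = best

    assignment = np.full(n, -1)
    iterations = 0
    for iterations in range(1, MAX_LLOYD_ITERATIONS + 1):
        new_assignment = _assign(G, centroids, config)
        new_assignment = _repair_empty(G, centroids, new_assignment)
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        centroids = np.vstack([G[assignment == k].mean(axis=0) for k in range(p)])
    # final pass keeps the assignment optimal w.r.t. the final centroids even
    # when the loop exhausted its budget (the similarity factor can oscillate)
    assignment = _repair_empty(G, centroids, _assign(G, centroids, config))

    aggregates = np.vstack([G[assignment == k].mean(axis=0) for k in range(p)])
    final_chi = chi_score(G, centroids, assignment) if n > p else float("nan")
    return ClusterAssignment(centroids, assignment, aggregates, final_chi,
                             iterations, ids, candidate_chis)
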