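"""Temporal causal graph construction and graph-feature extraction.

Edges are lagged inner products of z-scored series (lagged Pearson
correlations), computed for every ordered node pair and every lag up to
``max_lag``; per pair the single best lag is retained. Retained weights are
normalized by the global maximum absolute weight, and an edge enters the
adjacency only when its raw correlation magnitude clears the causality
threshold (operating band 0.3-0.6) after a minimum-edge-weight pre-filter.
Per-node graph features (degrees, weighted degree, edge confidence, strongly
connected components, causal chain lengths, temporal 2-chain motifs) feed the
node matrix alongside the preprocessed feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ArgumentError, DataError

TCG_FEATURE_NAMES = (
    "in_degree", "out_degree", "weighted_degree", "mean_edge_weight",
    "max_edge_weight", "edge_confidence", "scc_size", "chain_length",
    "motif_2chain",
)


@dataclass
class TemporalCausalGraph:
    nodes: list[str]
    max_lag: int
    threshold: float
    #: (source, target) -> (lag, raw weight, normalized weight) for the best lag
    best_edges: dict[tuple[int, int], tuple[int, float, float]]
    #: adjacency[target, source] = normalized weight of a retained edge, else 0
    adjacency: np.ndarray
    min_edge_weight: float = 0.05
    pruning_ratio: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def retained_edges(self) -> list[tuple[int, int, int, float]]:
        """(source, target, lag, normalized weight) for nonzero adjacency entries."""
        out = []
        for (s, t), (lag, _, w) in sorted(self.best_edges.items()):
            if self.adjacency[t, s] != 0.0:
                out.append((s, t, lag, w))
        return out

    def to_edge_tsv(self) -> str:
        lines = ["source\ttarget\tlag\tweight\tnormalized_weight\tretained"]
        for (s, t), (lag, raw, w) in sorted(self.best_edges.items()):
            kept = int(self.adjacency[t, s] != 0.0)
            lines.append(f"{self.nodes[s]}\t{self.nodes[t]}\t{lag}\t{raw:.10g}\t{w:.10g}\t{kept}")
        return "\n".join(lines) + "\n"


def standardize(series: np.ndarray) -> np.ndarray:
    """z-score a series (sample sd); a constant series maps to zeros.

    With ddof=1 the squared z-scores sum to nT-1, so the lag-weight of a
    series against a delayed copy of itself is bounded by 1.
    """
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def lagged_edge_weight(series_ab: np.ndarray, series_mn: np.ndarray, lag: int,
                       standardize_first: bool = True) -> float:
    """Lagged edge weight (1/(nT-1)) * sum_t source(t-lag) * target(t).

    With z-scored inputs this is (up to the edge-effect truncation) the lag-
    ``lag`` Pearson correlation between source and target.
    """
    a = np.asarray(series_ab, dtype=float)
    b = np.asarray(series_mn, dtype=float)
    nT = len(a)
    if len(b) != nT:
        raise DataError("series must have equal length")
    if not (1 <= lag < nT):
        raise ArgumentError(f"lag must satisfy 1 <= lag < nT, got lag={lag}, nT={nT}")
    if standardize_first:
        a, b = standardize(a), standardize(b)
    return float(np.dot(a[: nT - lag], b[lag:]) / (nT - 1))


def _pairwise_weights(panel: np.ndarray, max_lag: int) -> np.ndarray:
    """weights[lag-1, source, target] over z-scored columns of the panel."""
    nT, n = panel.shape
    z = np.column_stack([standardize(panel[:, j]) for j in range(n)])
    w = np.empty((max_lag, n, n))
    for lag in range(1, max_lag + 1):
        w[lag - 1] = z[: nT - lag].T @ z[lag:] / (nT - 1)
    return w


def build_tcg(panel: np.ndarray, max_lag: int = 3, threshold: float = 0.3,
              min_edge_weight: float = 0.05, pruning_ratio: float | None = None,
              window: int | None = None, node_names: list[str] | None = None) -> TemporalCausalGraph:
    """Construct the thresholded temporal causal graph of a panel.

    For every ordered pair the best lag (largest |weight|) up to ``max_lag``
    is retained; weights are normalized by the global max |weight|; an edge
    survives when its raw |weight| >= max(threshold, min_edge_weight). When
    ``window`` is set (cross-sectional tables with pseudo-time = record
    order), weights are averaged over sliding windows of that length with
    stride 1. Optional ``pruning_ratio`` drops the weakest surviving edges so
    at most (1 - ratio) of candidate pairs remain.
    """
    panel = np.asarray(panel, dtype=float)
    nT, n = panel.shape
    if max_lag < 1:
        raise ArgumentError("max_lag must be >= 1")
    if not (0.0 < threshold < 1.0):
        raise ArgumentError("threshold must lie in (0, 1)")
    if nT < max_lag + 2:
        raise DataError(f"need at least max_lag + 2 = {max_lag + 2} time steps, got {nT}")
    if window is not None and window < max_lag + 2:
        raise ArgumentError("window must be >= max_lag + 2")

    if window is None or window >= nT:
        weights = _pairwise_weights(panel, max_lag)
    else:
        acc = np.zeros((max_lag, n, n))
        n_win = nT - window + 1
        for start in range(n_win):
            acc += _pairwise_weights(panel[start: start + window], max_lag)
        weights = acc / n_win

    # best lag per ordered pair, self-pairs excluded
    best_edges: dict[tuple[int, int], tuple[int, float, float]] = {}
    abs_w = np.abs(weights)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            lag_idx = int(np.argmax(abs_w[:, s, t]))
            best_edges[(s, t)] = (lag_idx + 1, float(weights[lag_idx, s, t]), 0.0)

    max_abs = max((abs(raw) for _, raw, _ in best_edges.values()), default=0.0)
    scale = max_abs if max_abs > 0 else 1.0
    adjacency = np.zeros((n, n))
    cutoff = max(threshold, min_edge_weight)
    for (s, t), (lag, raw, _) in best_edges.items():
        norm = raw / scale
        best_edges[(s, t)] = (lag, raw, norm)
        if abs(raw) >= cutoff:
            adjacency[t, s] = norm

    if pruning_ratio is not None:
        if not (0.0 <= pruning_ratio < 1.0):
            raise ArgumentError("pruning_ratio must lie in [0, 1)")
        survivors = [(abs(adjacency[t, s]), s, t) for (s, t) in best_edges
                     if adjacency[t, s] != 0.0]
        keep = int(np.floor((1.0 - pruning_ratio) * len(best_edges)))
        if len(survivors) > keep:
            survivors.sort(reverse=True)
            for _, s, t in survivors[keep:]:
                adjacency[t, s] = 0.0

    names = node_names or [f"node_{i}" for i in range(n)]
    return TemporalCausalGraph(names, max_lag, threshold, best_edges, adjacency,
                               min_edge_weight, pruning_ratio)


def extract_tcg_features(graph: TemporalCausalGraph) -> np.ndarray:
    """Per-node graph features on the thresholded adjacency, shape (n, l).

    Columns follow ``TCG_FEATURE_NAMES``: in/out degree, weighted degree
    (sum of |incident normalized weights|), mean and max |incident weight|,
    edge confidence (max |incident weight|, already in [0, 1]), strongly-
    connected-component size, longest causal chain length from the node
    (cycles: SCC size - 1 within the component), and the count of 2-chain
    motifs a->b->c passing through the node.
    """
    n = graph.n_nodes
    A = graph.adjacency  # A[t, s] != 0 for edge s -> t
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for t in range(n):
        for s in range(n):
            if A[t, s] != 0.0:
                G.add_edge(s, t, weight=abs(A[t, s]))

    feats = np.zeros((n, len(TCG_FEATURE_NAMES)))
    scc_id = {}
    scc_size = {}
    for comp in nx.strongly_connected_components(G):
        for v in comp:
            scc_id[v] = min(comp)
            scc_size[v] = len(comp)

    # longest path in the condensation DAG, then add (scc size - 1) per node
    cond = nx.condensation(G)
    order = list(nx.topological_sort(cond))
    longest_from = {c: 0 for c in cond.nodes}
    for c in reversed(order):
        members = cond.nodes[c]["members"]
        internal = len(members) - 1
        best = 0
        for succ in cond.successors(c):
            best = max(best, longest_from[succ] + 1 + len(cond.nodes[succ]["members"]) - 1)
        longest_from[c] = internal + best

    node_to_comp = {}
    for c in cond.nodes:
        for v in cond.nodes[c]["members"]:
            node_to_comp[v] = c

    for v in range(n):
        incident = [abs(d["weight"]) for _, _, d in G.in_edges(v, data=True)]
        incident += [abs(d["weight"]) for _, _, d in G.out_edges(v, data=True)]
        in_deg, out_deg = G.in_degree(v), G.out_degree(v)
        motifs = in_deg * out_deg  # 2-chains a->v->c through v
        feats[v] = (
            in_deg, out_deg, float(np.sum(incident)),
            float(np.mean(incident)) if incident else 0.0,
            float(np.max(incident)) if incident else 0.0,
            float(np.max(incident)) if incident else 0.0,
            scc_size[v], longest_from[node_to_comp[v]], motifs,
        )
    return feats


def build_node_matrix(F: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Concatenate preprocessed features with a per-record TCG feature summary.

    ``F`` is (records x features), ``N`` is (features x l) per-feature graph
    statistics. Each record's summary is the feature-value-weighted mean of
    the rows of ``N`` (a record dominated by feature j inherits j's graph
    profile); an all-zero record gets a zero summary. Output is (records x
    (|F| + l)).
    """
    F = np.asarray(F, dtype=float)
    N = np.asarray(N, dtype=float)
    if F.ndim != 2 or N.ndim != 2 or F.shape[1] != N.shape[0]:
        raise DataError(f"feature/TCG dimension mismatch: F has {F.shape[1] if F.ndim == 2 else '?'} "
                        f"columns, N has {N.shape[0] if N.ndim == 2 else '?'} rows")
    if not (np.isfinite(F).all() and np.isfinite(N).all()):
        raise DataError("non-finite entries in node-matrix inputs")
    totals = F.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0.0, 1.0, totals)
    summary = (F @ N) / safe
    return np.hstack([F, summary])
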