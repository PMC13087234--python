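"""Mean-centering-normalized graph neural network for clinical event prediction.

Records of the node matrix become graph nodes, connected to their k nearest
neighbours by cosine similarity (symmetrized, self-loops added). Each hidden
layer performs mean-neighbourhood aggregation, an affine transform with ReLU,
a residual node update, and mean-centering normalization (MCN) of the node
features — the centering counteracts over-smoothing by removing the shared
drift component that repeated averaging accumulates. A ReLU readout and a
softmax head produce two-class probabilities (normal vs clinical event)
trained with cross-entropy under Adam.

The network is small (default 3 layers, width 32), so forward and backward
passes are written directly in numpy; gradients flow through aggregation
(multiplication by the transposed averaging operator), ReLU masks, residual
sums, and the centering map, whose Jacobian is I - (1/n) 11^T per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, ConfigurationError, DataError


def split_counts(n_records: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Train/test sizes: floor(train_fraction * n) and the remainder."""
    train = int(np.floor(train_fraction * n_records))
    return train, n_records - train


# ---------------------------------------------------------------------------
# graph construction

def build_ehr_graph(K: np.ndarray, k_neighbours: int = 8) -> np.ndarray:
    """k-nearest-neighbour graph over record rows by cosine similarity.

    Returns the dense 0/1 symmetric adjacency with unit diagonal (self-loops).
    ``k_neighbours = 0`` yields the identity.
    """
    K = np.asarray(K, dtype=float)
    if not np.isfinite(K).all():
        raise DataError("node matrix contains non-finite entries")
    n = K.shape[0]
    if k_neighbours >= n:
        raise ArgumentError(f"k_neighbours ({k_neighbours}) must be < number of records ({n})")
    A = np.eye(n)
    if k_neighbours > 0:
        norms = np.linalg.norm(K, axis=1)
        safe = np.where(norms == 0.0, 1.0, norms)
        Z = K / safe[:, None]
        sim = Z @ Z.T
        np.fill_diagonal(sim, -np.inf)
        nbrs = np.argpartition(-sim, k_neighbours - 1, axis=1)[:, :k_neighbours]
        rows = np.repeat(np.arange(n), k_neighbours)
        A[rows, nbrs.ravel()] = 1.0
        A = np.maximum(A, A.T)  # symmetrize
    return A


def mcn(H: np.ndarray) -> np.ndarray:
    """Mean-centering normalization: subtract each column's across-node mean."""
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise DataError("empty feature matrix")
    return H - H.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# parameters

@dataclass
class GNNParams:
    """Weights of the embedding, message-passing layers, readout and head."""

    embed: tuple[np.ndarray, np.ndarray]  # input projection to hidden width
    layers: list[tuple[np.ndarray, np.ndarray]]  # (W, b) per hidden layer
    readout: tuple[np.ndarray, np.ndarray]
    head: tuple[np.ndarray, np.ndarray]

    @classmethod
    def init(cls, n_features: int, hidden: int, n_layers: int, rng: np.random.Generator,
             n_classes: int = 2) -> "GNNParams":
        if not (2 <= n_layers <= 4):
            raise ConfigurationError("layer count must lie in 2-4")

        def he(fan_in, fan_out):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

        layers = [(he(hidden, hidden), np.zeros(hidden)) for _ in range(n_layers)]
        return cls(embed=(he(n_features, hidden), np.zeros(hidden)),
                   layers=layers,
                   readout=(he(hidden, hidden), np.zeros(hidden)),
                   head=(he(hidden, n_classes), np.zeros(n_classes)))

    def _all(self) -> list[np.ndarray]:
        out = [*self.embed]
        for W, b in self.layers:
            out += [W, b]
        out += [*self.readout, *self.head]
        return out

    @property
    def n_parameters(self) -> int:
        return sum(a.size for a in self._all())

    def flatten(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._all()])

    def unflatten_like(self, vec: np.ndarray) -> "GNNParams":
        """Rebuild a GNNParams with this object's shapes from a flat vector."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_parameters:
            raise DataError(f"flat vector length {vec.size} != parameter count {self.n_parameters}")
        pieces, pos = [], 0
        for a in self._all():
            pieces.append(vec[pos: pos + a.size].reshape(a.shape))
            pos += a.size
        k = len(self.layers)
        return GNNParams(embed=(pieces[0], pieces[1]),
                         layers=[(pieces[2 + 2 * i], pieces[3 + 2 * i]) for i in range(k)],
                         readout=(pieces[2 + 2 * k], pieces[3 + 2 * k]),
                         head=(pieces[4 + 2 * k], pieces[5 + 2 * k]))

    def add(self, delta: np.ndarray) -> "GNNParams":
        return self.unflatten_like(self.flatten() + delta)

    def copy(self) -> "GNNParams":
        return self.unflatten_like(self.flatten())

    def to_json_dict(self) -> dict:
        return {
            "embed": [self.embed[0].tolist(), self.embed[1].tolist()],
            "layers": [[W.tolist(), b.tolist()] for W, b in self.layers],
            "readout": [self.readout[0].tolist(), self.readout[1].tolist()],
            "head": [self.head[0].tolist(), self.head[1].tolist()],
        }


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    hidden: int = 32
    n_layers: int = 3
    k_neighbours: int = 8
    seed: int = 0

    def validate(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs", "hidden", "n_layers"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# forward / backward

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gnn_forward(A: np.ndarray, X: np.ndarray, params: GNNParams,
                return_cache: bool = False):
    """Full forward pass; returns per-node class probabilities.

    A linear embedding maps the input width to the hidden width; every
    message-passing layer then performs the residual node update before
    centering: h <- mcn(h + relu(P h W + b)), with P the row-normalized
    adjacency (mean aggregation over neighbours including the self-loop).
    """
    A = np.asarray(A, dtype=float)
    P = A / A.sum(axis=1, keepdims=True)
    X = np.asarray(X, dtype=float)
    W0, b0 = params.embed
    H = X @ W0 + b0
    cache = {"P": P, "X": X, "H": [H], "Z": [], "agg": []}
    for W, b in params.layers:
        agg = P @ H
        Z = agg @ W + b
        M = np.maximum(Z, 0.0)
        H = mcn(H + M)
        cache["agg"].append(agg)
        cache["Z"].append(Z)
        cache["H"].append(H)
    Wr, br = params.readout
    Zr = H @ Wr + br
    U = np.maximum(Zr, 0.0)
    Wh, bh = params.head
    logits = U @ Wh + bh
    probs = _softmax(logits)
    if return_cache:
        cache.update(Zr=Zr, U=U, logits=logits, probs=probs)
        return probs, cache
    return probs


def _backward(params: GNNParams, cache: dict, y: np.ndarray) -> GNNParams:
    """Gradient of mean cross-entropy w.r.t. every parameter tensor."""
    n = len(y)
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    U, Zr = cache["U"], cache["Zr"]
    Wh, _ = params.head
    dWh = U.T @ dlogits
    dbh = dlogits.sum(axis=0)
    dU = dlogits @ Wh.T
    dZr = dU * (Zr > 0)
    Wr, _ = params.readout
    H_last = cache["H"][-1]
    dWr = H_last.T @ dZr
    dbr = dZr.sum(axis=0)
    dH = dZr @ Wr.T

    P = cache["P"]
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params.layers)
    for i in reversed(range(len(params.layers))):
        W, _ = params.layers[i]
        # through mcn: J = I - (1/n) 11^T per column
        dPre = dH - dH.mean(axis=0, keepdims=True)
        dZ = dPre * (cache["Z"][i] > 0)
        dW = cache["agg"][i].T @ dZ
        db = dZ.sum(axis=0)
        dH = P.T @ (dZ @ W.T) + dPre  # aggregation + residual branches
        grads[i] = (dW, db)
    dW0 = cache["X"].T @ dH
    db0 = dH.sum(axis=0)
    return GNNParams(embed=(dW0, db0), layers=grads, readout=(dWr, dbr), head=(dWh, dbh))


class _Adam:
    def __init__(self, n: int, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model / results

@dataclass
class GNNResults:
    """Fit results: final parameters, the round's gradient, and diagnostics."""

    params: GNNParams
    gradient: np.ndarray  # flattened parameter delta of the fit
    train_accuracy: float
    test_accuracy: float
    loss_history: list[float]
    config: TrainConfig
    n_train: int
    n_test: int
    confusion: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "MCN-GNN fit results",
            "===================",
            f"layers: {self.config.n_layers}  hidden: {self.config.hidden}  "
            f"k_neighbours: {self.config.k_neighbours}",
            f"parameters: {self.params.n_parameters}",
            f"epochs: {self.config.epochs}  batch size: {self.config.batch_size}  "
            f"lr: {self.config.learning_rate} (Adam, cross-entropy)",
            f"train n: {self.n_train}  test n: {self.n_test}",
            f"train accuracy: {self.train_accuracy:.4f}",
            f"test accuracy:  {self.test_accuracy:.4f}",
            f"final loss: {self.loss_history[-1]:.4f}" if self.loss_history else "final loss: n/a",
        ]
        return "\n".join(lines)


class GNNClassifier:
    """Two-class MCN-GNN over a node matrix, statsmodels-style.

    Construct from the (records x features) node matrix ``K`` and binary
    labels ``y``; ``fit()`` returns a :class:`GNNResults` carrying the final
    parameters, the flattened parameter delta of the fit (the "gradient"
    shipped to the federation server), accuracies and the loss history.
    """

    def __init__(self, K: np.ndarray, y: np.ndarray, config: TrainConfig | None = None):
        self.K = np.asarray(K, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.config = config or TrainConfig()
        self.config.validate()
        if len(np.unique(self.y)) < 2:
            raise DataError("training labels contain a single class")

    @classmethod
    def from_dataframe(cls, df, label_column: str = "event",
                       config: TrainConfig | None = None) -> "GNNClassifier":
        features = [c for c in df.columns if c != label_column]
        return cls(df[features].to_numpy(float), df[label_column].to_numpy(int), config)

    def init_params(self) -> GNNParams:
        rng = np.random.default_rng(self.config.seed)
        return GNNParams.init(self.K.shape[1], self.config.hidden,
                              self.config.n_layers, rng)

    def fit(self, params: GNNParams | None = None, epochs: int | None = None,
            split: bool = True) -> GNNResults:
        """Mini-batch Adam training; 80/20 split with train n = floor(0.8 h)."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = params.copy() if params is not None else self.init_params()
        epochs = epochs if epochs is not None else cfg.epochs
        n = len(self.y)
        perm = rng.permutation(n)
        n_train = int(np.floor(0.8 * n)) if split else n
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if len(np.unique(self.y[train_idx])) < 2:
            raise DataError("training split contains a single class")

        theta0 = params.flatten()
        theta = theta0.copy()
        adam = _Adam(theta.size, cfg.learning_rate)
        loss_history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n_train)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_train, cfg.batch_size):
                batch = train_idx[order[start: start + cfg.batch_size]]
                if len(batch) < 2:
                    continue
                Kb, yb = self.K[batch], self.y[batch]
                k = min(cfg.k_neighbours, len(batch) - 1)
                A = build_ehr_graph(Kb, k)
                p = params.unflatten_like(theta)
                probs, cache = gnn_forward(A, Kb, p, return_cache=True)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
                grads = _backward(p, cache, yb)
                theta = adam.step(theta, grads.flatten())
                epoch_loss += loss
                n_batches += 1
            loss_history.append(epoch_loss / max(n_batches, 1))

        final = params.unflatten_like(theta)
        train_acc = self.score(final, train_idx)
        test_acc = self.score(final, test_idx) if len(test_idx) else float("nan")
        conf = self.confusion(final, test_idx if len(test_idx) else train_idx)
        return GNNResults(final, theta - theta0, train_acc, test_acc,
                          loss_history, cfg, len(train_idx), len(test_idx), conf)

    def predict_proba(self, params: GNNParams, idx: np.ndarray | None = None) -> np.ndarray:
        rows = self.K if idx is None else self.K[idx]
        k = min(self.config.k_neighbours, len(rows) - 1)
        A = build_ehr_graph(rows, max(k, 0))
        return gnn_forward(A, rows, params)

    def score(self, params: GNNParams, idx: np.ndarray | None = None) -> float:
        y = self.y if idx is None else self.y[idx]
        probs = self.predict_proba(params, idx)
        return float(np.mean(probs.argmax(axis=1) == y))

    def confusion(self, params: GNNParams, idx: np.ndarray | None = None) -> dict[str, int]:
        y = self.y if idx is None else self.y[idx]
        pred = self.predict_proba(params, idx).argmax(axis=1)
        return {"TP": int(np.sum((pred == 1) & (y == 1))),
                "TN": int(np.sum((pred == 0) & (y == 0))),
                "FP": int(np.sum((pred == 1) & (y == 0))),
                "FN": int(np.sum((pred == 0) & (y == 1)))}


def train_local(table, tcg_features: np.ndarray | None, config: TrainConfig
                ) -> tuple[GNNParams, np.ndarray, dict]:
    """Train one hospital's local model on a preprocessed table.

    Builds the node matrix (preprocessed features + TCG feature summary),
    fits the MCN-GNN, and returns (params, flattened round gradient R,
    metrics dict). ``tcg_features`` may be None to train on features alone.
    """
    from .tcg import build_node_matrix

    F = table.features
    K = build_node_matrix(F, tcg_features) if tcg_features is not None else F
    model = GNNClassifier(K, table.labels, config)
    res = model.fit()
    metrics = {"train_accuracy": res.train_accuracy, "test_accuracy": res.test_accuracy,
               "n_train": res.n_train, "n_test": res.n_test,
               "loss_history": res.loss_history, "confusion": res.confusion}
    return res.params, res.gradient, metrics
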