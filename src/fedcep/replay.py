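"""Continual update by polynomial-decay experience replay (MEPDR).

Each round the hospital blends a replay gradient G — a decay-weighted mean
of buffered past gradients — with the incoming global gradient Y using the
polynomial decay weight R(b) = 1/(1 + lambda*b)^tau: params += R*G + (1-R)*Y.
The buffer stores gradients (not raw examples, which would undo the privacy
story); at sampling time each entry is weighted by R(age), the decay
evaluated at the entry's age in rounds, so early-task entries lose influence
instead of dominating the replay.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError


def polynomial_decay(lam: float, tau: float, b: int | float) -> float:
    """R = 1 / (1 + lambda*b)^tau; R(0) = 1, strictly decreasing in b."""
    if lam <= 0 or tau <= 0:
        raise ArgumentError("lambda and tau must be > 0")
    if b < 0:
        raise ArgumentError("iteration counter b must be >= 0")
    return 1.0 / (1.0 + lam * b) ** tau


def blend(G: np.ndarray, Y: np.ndarray, R: float) -> np.ndarray:
    """A = R*G + (1-R)*Y, elementwise convex combination."""
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape != Y.shape:
        raise DataError("gradient length mismatch in blend")
    if not (0.0 <= R <= 1.0):
        raise ArgumentError("blend weight must lie in [0, 1]")
    return R * G + (1.0 - R) * Y


@dataclass
class DecayConfig:
    lam: float = 0.05
    tau: float = 1.0
    b: int = 0  # total iteration counter

    def validate(self) -> None:
        if self.b < 0:
            raise ArgumentError("b must be >= 0")
        polynomial_decay(self.lam, self.tau, self.b)

    def current(self) -> float:
        return polynomial_decay(self.lam, self.tau, self.b)


@dataclass
class ReplayBuffer:
    """Bounded store of past gradients; sampling weights decay with age."""

    capacity: int = 20
    lam: float = 0.05
    tau: float = 1.0
    entries: deque = field(default_factory=deque)  # (gradient, insertion round)

    def push(self, gradient: np.ndarray, round_index: int) -> None:
        self.entries.append((np.asarray(gradient, dtype=float).copy(), int(round_index)))
        while len(self.entries) > self.capacity:
            self.entries.popleft()

    def __len__(self) -> int:
        return len(self.entries)

    def sampling_weights(self, current_round: int) -> np.ndarray:
        """Normalized R(age) per entry, age = current_round - insertion round."""
        if not self.entries:
            return np.empty(0)
        w = np.array([polynomial_decay(self.lam, self.tau, max(current_round - r, 0))
                      for _, r in self.entries])
        return w / w.sum()

    def replay_gradient(self, length: int, current_round: int) -> np.ndarray:
        """Decay-weighted mean of buffered gradients; zeros when empty."""
        if not self.entries:
            return np.zeros(length)
        w = self.sampling_weights(current_round)
        return np.sum([wi * g for (g, _), wi in zip(self.entries, w)], axis=0)


def continual_update(local_params: np.ndarray, buffer: ReplayBuffer,
                     Y: np.ndarray, config: DecayConfig,
                     current_gradient: np.ndarray | None = None) -> np.ndarray:
    """One MEPDR step: blend replay with the global gradient and advance b.

    G is the decay-weighted mean of the buffered gradients (zero when the
    buffer is empty, i.e. pure global adoption); the returned flat parameter
    vector is params + A with A = R(b)*G + (1-R(b))*Y. ``config.b`` advances
    and the current round's gradient (default: the blended step A) is pushed
    into the buffer.
    """
    local_params = np.asarray(local_params, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if local_params.shape != Y.shape:
        raise DataError("parameter/gradient length mismatch")
    R = config.current()
    G = buffer.replay_gradient(len(Y), config.b)
    A = blend(G, Y, R)
    updated = local_params + A
    pushed = A if current_gradient is None else np.asarray(current_gradient, dtype=float)
    buffer.push(pushed, config.b)
    config.b += 1
    return updated
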