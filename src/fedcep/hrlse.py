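"""Gradient privacy: robust log scaling + additively homomorphic masking.

Robust log scaling (RLS) compresses large gradient magnitudes elementwise,
x -> x * ln(|x|/q + 1), before protection, limiting the growth of masked
values under repeated additions. Protection itself is seed-derived additive
masking: a per-key secret seed and a fresh nonce feed a SHA-256 counter-mode
PRG whose real-valued mask is added to the scaled gradient. Masked vectors
can be summed coordinate-wise and the sum unmasked with the masks of all
contributing nonces — the additive homomorphism the aggregation server
relies on. The mask width is scaled to the plaintext's magnitude regime
(default 1e3 x RMS) and travels with the cipher record so the holder of the
secret seed can regenerate the mask; the width itself therefore leaks a
coarse magnitude scale, which is documented and accepted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ArgumentError, DataError, KeyError_, NumericError, SecurityError

MASK_WIDTH_FACTOR = 1e3


# ---------------------------------------------------------------------------
# robust log scaling

def robust_log_scale(R: np.ndarray, q: float = 1.0) -> np.ndarray:
    """Elementwise x * ln(|x|/q + 1); sign-preserving, monotone in |x|."""
    if q <= 0:
        raise ArgumentError("q must be > 0")
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise DataError("gradient contains non-finite values")
    return R * np.log1p(np.abs(R) / q)


def _rls_scalar(x: float, q: float) -> float:
    return x * np.log1p(x / q)


def inverse_rls(scaled: np.ndarray, q: float = 1.0, tol: float = 1e-9,
                max_iter: int = 200) -> np.ndarray:
    """Invert robust log scaling by monotone bracketing on |value|."""
    if q <= 0:
        raise ArgumentError("q must be > 0")
    scaled = np.asarray(scaled, dtype=float)
    out = np.zeros_like(scaled)
    flat = scaled.ravel()
    res = out.ravel()
    for i, v in enumerate(flat):
        if v == 0.0:
            continue
        target = abs(v)
        hi = max(1.0, target, q)
        it = 0
        while _rls_scalar(hi, q) < target:
            hi *= 2.0
            it += 1
            if it > max_iter:
                raise NumericError("bracketing failed in inverse_rls")
        root = brentq(lambda x: _rls_scalar(x, q) - target, 0.0, hi, xtol=tol)
        res[i] = np.copysign(root, v)
    return out


# ---------------------------------------------------------------------------
# keys and masking

def _prg_floats(seed_bytes: bytes, nonce: str, n: int) -> np.ndarray:
    """Deterministic uniform(0,1) stream from SHA-256 in counter mode."""
    out = np.empty(n)
    base = hashlib.sha256(seed_bytes + b"|" + nonce.encode()).digest()
    i = 0
    counter = 0
    while i < n:
        block = hashlib.sha256(base + counter.to_bytes(8, "big")).digest()
        for off in range(0, 32, 8):
            if i >= n:
                break
            out[i] = int.from_bytes(block[off: off + 8], "big") / 2.0 ** 64
            i += 1
        counter += 1
    return out


@dataclass
class KeyPair:
    """Additive-masking key pair.

    The public part carries the scheme id and the noise parameters (d, e) —
    PRG domain-separation material derivable by anyone; the private part is
    the secret mask seed, never serialized into cipher records.
    """

    key_id: str
    d: int
    e: int
    _secret_seed: bytes = field(repr=False)
    _used_nonces: set = field(default_factory=set, repr=False)

    def public(self) -> dict:
        return {"scheme": "additive-mask-prg", "key_id": self.key_id,
                "d": self.d, "e": self.e}


def keygen(master_seed: int, key_id: str | None = None) -> KeyPair:
    """Derive a key pair deterministically from a master seed."""
    material = hashlib.sha256(f"fedcep-keygen|{master_seed}".encode()).digest()
    d = int.from_bytes(material[:4], "big")
    e = int.from_bytes(material[4:8], "big")
    secret = hashlib.sha256(b"secret|" + material).digest()
    kid = key_id or hashlib.sha256(b"kid|" + material).hexdigest()[:16]
    return KeyPair(kid, d, e, secret)


@dataclass
class CipherGradient:
    """Masked gradient vector plus the metadata needed to unmask it.

    ``components`` lists (nonce, width) pairs — one for a fresh encryption,
    several after homomorphic additions.
    """

    values: np.ndarray
    key_id: str
    components: list[tuple[str, float]]
    rls: bool = True

    @property
    def length(self) -> int:
        return len(self.values)

    def to_json_dict(self) -> dict:
        return {"key_id": self.key_id, "length": self.length, "rls": self.rls,
                "components": [[n, w] for n, w in self.components],
                "values": self.values.tolist()}


def _mask(keys: KeyPair, nonce: str, n: int, width: float) -> np.ndarray:
    seed = keys._secret_seed + keys.d.to_bytes(4, "big") + keys.e.to_bytes(4, "big")
    return (_prg_floats(seed, nonce, n) - 0.5) * 2.0 * width


def encrypt(scaled: np.ndarray, keys: KeyPair, nonce: str, rls: bool = True) -> CipherGradient:
    """Mask a (scaled) gradient vector; the nonce must be fresh per key."""
    if nonce in keys._used_nonces:
        raise SecurityError(f"nonce {nonce!r} already used with key {keys.key_id}")
    keys._used_nonces.add(nonce)
    scaled = np.asarray(scaled, dtype=float)
    rms = float(np.sqrt(np.mean(scaled ** 2))) if scaled.size else 0.0
    width = MASK_WIDTH_FACTOR * max(rms, 1e-12)
    masked = scaled + _mask(keys, nonce, scaled.size, width)
    return CipherGradient(masked, keys.key_id, [(nonce, width)], rls)


def add_ciphers(a: CipherGradient, b: CipherGradient) -> CipherGradient:
    """Homomorphic addition of two cipher gradients under the same key."""
    if a.key_id != b.key_id:
        raise KeyError_("cannot add ciphertexts under different keys")
    if a.length != b.length:
        raise DataError("ciphertext length mismatch")
    return CipherGradient(a.values + b.values, a.key_id,
                          a.components + b.components, a.rls and b.rls)


def decrypt(cipher: CipherGradient, keys: KeyPair) -> np.ndarray:
    """Remove the masks of every contributing nonce."""
    if cipher.key_id != keys.key_id:
        raise KeyError_(f"unknown key id {cipher.key_id!r}")
    out = cipher.values.astype(float).copy()
    for nonce, width in cipher.components:
        out -= _mask(keys, nonce, cipher.length, width)
    return out


def protect_gradient(R: np.ndarray, keys: KeyPair, nonce: str, q: float = 1.0) -> CipherGradient:
    """RLS then mask: the full hospital-side protection step."""
    return encrypt(robust_log_scale(R, q), keys, nonce, rls=True)


def recover_gradient(cipher: CipherGradient, keys: KeyPair, q: float = 1.0) -> np.ndarray:
    """Unmask then invert RLS: the full server-side recovery step."""
    plain = decrypt(cipher, keys)
    return inverse_rls(plain, q) if cipher.rls else plain
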