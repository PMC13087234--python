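"""Hospital authentication: exponential-probing hash and signature check.

A hospital's id string is encoded as a big integer, reduced modulo a large
prime, and pushed through the exponential function at fixed precision to
form the hash gamma; the signature D adds the canonical numeric encodings of
the id and the public key. The server recomputes both quantities from its
registration records and authenticates (J1) exactly when the signatures are
equal — all arithmetic is carried out on scaled integers so equality is
exact, never a float comparison. To keep exp bounded, the modular residue is
reduced once more modulo 64 before exponentiation.

Registration stores a salted SHA-256 password digest; login checks digest
equality.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass

from .errors import ArgumentError, NumericError

DEFAULT_P = 2 ** 61 - 1  # Mersenne prime
DEFAULT_U = 1
DEFAULT_SCALE = 10 ** 6
EXP_REDUCTION = 64  # exp argument bound: residue is reduced mod 64


def _encode_int(s: str) -> int:
    """Canonical big-integer encoding of a string's UTF-8 bytes."""
    if not s:
        raise ArgumentError("cannot encode an empty string")
    return int.from_bytes(s.encode("utf-8"), "big")


def _encode_key(public_key: dict | str | int) -> int:
    """Canonical numeric encoding of a public key (digest of its repr)."""
    if isinstance(public_key, int):
        return public_key
    text = repr(sorted(public_key.items())) if isinstance(public_key, dict) else str(public_key)
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:16], "big")


def expr_hash(T: str, u: int = DEFAULT_U, p: int = DEFAULT_P,
              scale: int = DEFAULT_SCALE) -> int:
    """Exponential-probing hash, returned as an integer in units of 1/scale.

    gamma = u + round(exp((int(T) mod p) mod 64) * scale) / scale, carried as
    the scaled integer u*scale + round(exp(.)*scale) for exact comparisons.
    """
    if p < 2:
        raise ArgumentError("p must be a prime >= 2")
    if scale <= 0 or 10 ** round(math.log10(scale)) != scale:
        raise ArgumentError("scale must be a positive power of ten")
    residue = (_encode_int(T) % p) % EXP_REDUCTION
    try:
        val = math.exp(residue)
    except OverflowError as exc:  # unreachable with the mod-64 reduction
        raise NumericError("exp overflow in expr_hash") from exc
    return u * scale + round(val * scale)


@dataclass(frozen=True)
class HospitalIdentity:
    hospital_id: str
    password_digest: str  # salted SHA-256, hex
    salt: str
    public_key: dict

    @classmethod
    def register(cls, hospital_id: str, password: str, public_key: dict,
                 salt: bytes | None = None) -> "HospitalIdentity":
        if not hospital_id:
            raise ArgumentError("hospital id must be nonempty")
        salt = salt if salt is not None else os.urandom(16)
        digest = hashlib.sha256(salt + password.encode()).hexdigest()
        return cls(hospital_id, digest, salt.hex(), public_key)

    def check_password(self, password: str) -> bool:
        digest = hashlib.sha256(bytes.fromhex(self.salt) + password.encode()).hexdigest()
        return digest == self.password_digest


@dataclass(frozen=True)
class SignatureRecord:
    """Fixed-precision signature: all quantities are integers in 1/scale units."""

    hospital_id: str
    gamma: int
    D: int
    u: int = DEFAULT_U
    p: int = DEFAULT_P
    scale: int = DEFAULT_SCALE

    def to_json_dict(self) -> dict:
        return {"hospital_id": self.hospital_id, "gamma": str(self.gamma),
                "D": str(self.D), "u": self.u, "p": str(self.p), "scale": self.scale}


def sign(hospital_id: str, public_key: dict | str | int, u: int = DEFAULT_U,
         p: int = DEFAULT_P, scale: int = DEFAULT_SCALE) -> SignatureRecord:
    """D = numeric(T) + gamma + numeric(public key), on scaled integers."""
    gamma = expr_hash(hospital_id, u, p, scale)
    D = _encode_int(hospital_id) * scale + gamma + _encode_key(public_key) * scale
    return SignatureRecord(hospital_id, gamma, D, u, p, scale)


@dataclass(frozen=True)
class AuthResult:
    authenticated: bool  # True = J1, False = J2
    reason: str = ""

    J1 = property(lambda self: self.authenticated)
    J2 = property(lambda self: not self.authenticated)


def verify(client_record: SignatureRecord, claimed_id: str,
           public_key: dict | str | int) -> AuthResult:
    """Server-side recomputation and exact signature equality (J1/J2)."""
    try:
        server_record = sign(claimed_id, public_key, client_record.u,
                             client_record.p, client_record.scale)
    except ArgumentError:
        return AuthResult(False, "invalid id")
    if server_record.D == client_record.D:
        return AuthResult(True)
    return AuthResult(False, "signature mismatch")
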