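"""Append-only hash-chained transaction ledger.

Single-process stand-in for a permissioned blockchain: every framework step
(registration, login, local training, privacy preservation, authentication,
aggregation, global prediction, continual update) is recorded as a block
whose SHA-256 hash covers its index, the previous block's hash and the
canonical JSON of the transaction. The persistence layer exposes only append
and read; any external mutation of the JSONL file is detected by
verification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import LedgerError

ACTIONS = frozenset({
    "registration", "login", "local_training", "privacy_preservation",
    "authentication", "aggregation", "global_prediction", "continual_update",
})
GENESIS_PREV = "0" * 64


def payload_digest(payload) -> str:
    """SHA-256 hex of the canonical JSON serialization of a payload."""
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass(frozen=True)
class Transaction:
    actor: str
    action: str
    digest: str  # 64 lowercase hex chars
    timestamp: float

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise LedgerError(f"unknown action {self.action!r}")
        if not (len(self.digest) == 64 and all(c in "0123456789abcdef" for c in self.digest)):
            raise LedgerError("digest must be 64 lowercase hex characters")

    @classmethod
    def make(cls, actor: str, action: str, payload, timestamp: float = 0.0) -> "Transaction":
        return cls(actor, action, payload_digest(payload), timestamp)

    def canonical(self) -> str:
        return json.dumps({"actor": self.actor, "action": self.action,
                           "digest": self.digest, "timestamp": self.timestamp},
                          sort_keys=True, separators=(",", ":"))


def _block_hash(index: int, prev_hash: str, tx: Transaction) -> str:
    material = f"{index}|{prev_hash}|{tx.canonical()}"
    return hashlib.sha256(material.encode()).hexdigest()


@dataclass(frozen=True)
class LedgerBlock:
    index: int
    prev_hash: str
    transaction: Transaction
    block_hash: str

    def to_json(self) -> str:
        return json.dumps({"index": self.index, "prev_hash": self.prev_hash,
                           "transaction": json.loads(self.transaction.canonical()),
                           "block_hash": self.block_hash},
                          sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, line: str) -> "LedgerBlock":
        try:
            obj = json.loads(line)
            tx = Transaction(**obj["transaction"])
            return cls(obj["index"], obj["prev_hash"], tx, obj["block_hash"])
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise LedgerError(f"malformed ledger line: {exc}") from exc


class Ledger:
    """In-memory chain, optionally persisted as JSONL (one block per line)."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.blocks: list[LedgerBlock] = []
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    self.blocks.append(LedgerBlock.from_json(line))

    def __len__(self) -> int:
        return len(self.blocks)

    def append(self, tx: Transaction) -> LedgerBlock:
        index = len(self.blocks)
        prev = self.blocks[-1].block_hash if self.blocks else GENESIS_PREV
        block = LedgerBlock(index, prev, tx, _block_hash(index, prev, tx))
        line = block.to_json()  # serialize (and fail) before any mutation
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
        self.blocks.append(block)
        return block

    def record(self, actor: str, action: str, payload, timestamp: float = 0.0) -> LedgerBlock:
        return self.append(Transaction.make(actor, action, payload, timestamp))

    def verify(self) -> tuple[bool, int | None]:
        return verify_chain(self.blocks)


def verify_chain(blocks: list[LedgerBlock]) -> tuple[bool, int | None]:
    """True iff every block's hash recomputes and links; else (False, first bad index)."""
    prev = GENESIS_PREV
    for i, block in enumerate(blocks):
        if (block.index != i or block.prev_hash != prev
                or _block_hash(block.index, block.prev_hash, block.transaction) != block.block_hash):
            return False, i
        prev = block.block_hash
    return True, None
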