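"""Hash-chained, quorum-committed audit ledger.

A desk-scale stand-in for the consortium blockchain that coordinates the
swarm: each committed round appends one block whose SHA-256 hash covers the
previous block's hash and a canonical (key-sorted, whitespace-free) JSON
serialization of the round record — leader, participants, aggregate digest,
metrics snapshot, and the votes that committed it.  Any retroactive edit
breaks the chain at or after the edited block and is caught by
:func:`verify_chain`.

Consensus is simulated as a one-shot Practical-Byzantine-Fault-Tolerance
style quorum: a round commits iff affirmative votes reach
``floor(2n/3) + 1`` of the ``n`` registered nodes.  Smart-contract
governance reduces to ledger-enforced preconditions — only committed
payloads append, and only registered nodes may vote.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import LedgerError, UncommittedPayloadError

GENESIS_HASH = "0" * 64


def canonical_payload(payload: Mapping) -> str:
    """Key-sorted, whitespace-free JSON — the byte-exact hashing form."""
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def block_hash(prev_hash: str, payload: Mapping) -> str:
    data = prev_hash + "|" + canonical_payload(payload)
    return hashlib.sha256(data.encode()).hexdigest()


@dataclass
class Block:
    index: int
    prev_hash: str
    payload: dict
    hash: str


def commit_round(votes: Mapping[object, bool], nodes: Sequence[object]) -> bool:
    """PBFT-style quorum rule: commit iff yes-votes >= floor(2n/3) + 1.

    ``nodes`` is the registry of eligible voters; a vote from an
    unregistered node is an error.
    """
    if len(nodes) < 1:
        raise LedgerError("need at least one registered node")
    unknown = set(votes) - set(nodes)
    if unknown:
        raise LedgerError(f"votes from unregistered node(s) {sorted(map(str, unknown))}")
    quorum = (2 * len(nodes)) // 3 + 1
    return sum(bool(v) for v in votes.values()) >= quorum


class Ledger:
    """Append-only chain of committed round records."""

    def __init__(self, nodes: Sequence[object] = ()):
        self.nodes = list(nodes)
        self.blocks: list[Block] = []

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def head_hash(self) -> str:
        return self.blocks[-1].hash if self.blocks else GENESIS_HASH

    def append_block(self, payload: Mapping) -> Block:
        """Append a committed round record.

        The payload must carry a ``votes`` mapping that reaches quorum
        among the registered nodes; otherwise the append is refused.
        """
        payload = dict(payload)
        votes = payload.get("votes")
        if self.nodes:
            # payload vote keys are strings (canonical JSON form)
            registry = [str(n) for n in self.nodes]
            if votes is None or not commit_round(
                {str(k): v for k, v in votes.items()}, registry
            ):
                raise UncommittedPayloadError(
                    "payload not committed: quorum of registered nodes not reached"
                )
        prev = self.head_hash
        block = Block(
            index=len(self.blocks),
            prev_hash=prev,
            payload=payload,
            hash=block_hash(prev, payload),
        )
        self.blocks.append(block)
        return block

    def save(self, path: str | Path) -> None:
        """One block per line, canonical JSON — byte-stable round-trip."""
        lines = [
            json.dumps(
                {
                    "index": b.index,
                    "prev_hash": b.prev_hash,
                    "payload": b.payload,
                    "hash": b.hash,
                },
                sort_keys=True,
                separators=(",", ":"),
            )
            for b in self.blocks
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def load(cls, path: str | Path, nodes: Sequence[object] = ()) -> "Ledger":
        ledger = cls(nodes)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            ledger.blocks.append(
                Block(d["index"], d["prev_hash"], d["payload"], d["hash"])
            )
        return ledger


def verify_chain(ledger: Ledger) -> tuple[bool, int | None]:
    """Recompute every hash and link; return (ok, first bad index)."""
    prev = GENESIS_HASH
    for i, b in enumerate(ledger.blocks):
        if b.index != i or b.prev_hash != prev or b.hash != block_hash(prev, b.payload):
            return False, i
        prev = b.hash
    return True, None
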