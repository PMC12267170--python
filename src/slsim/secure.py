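"""Pairwise-mask secure aggregation seeded by Diffie-Hellman key agreement.

Every ordered node pair ``(i, j)`` agrees on a shared secret through a
classic modular-exponentiation Diffie-Hellman exchange; the secret seeds a
reproducible pseudo-random mask vector.  Node ``i`` submits

    masked_i = params_i + sum_{j > i} m(s_ij) - sum_{j < i} m(s_ij)

so the pair masks are antisymmetric and cancel exactly in the sum over all
participants: the aggregator recovers ``sum_i params_i`` without ever
seeing an individual update.  If any declared participant is missing, the
residual masks do not cancel and aggregation refuses to proceed.

Two numeric modes:

* **fixed-point** (default): values are quantized at scale ``2**20`` into
  64-bit integers and masks are drawn as bounded integers, which makes
  cancellation *exact* — bit-for-bit, not just to rounding error;
* **float**: masks are Gaussian; cancellation holds to ~1e-6 per
  coordinate.

The demo group is a fixed 64-bit safe prime.  This is a protocol
simulator: no claim of cryptographic strength is made, and a toy group
(p=23, g=5) is small enough to verify by hand.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import KeyExchangeError, MaskingError, MissingParticipantError

#: Fixed-point quantization scale (module default).
FIXED_POINT_SCALE = 2**20

#: Bound on fixed-point mask entries; 6 masks of this size plus the data
#: stay far inside int64.
_MASK_BOUND = 2**40

#: Standard deviation of float-mode masks; large enough that a single
#: masked update is statistically unrelated to its plain update.
_FLOAT_MASK_SD = 32.0


@dataclass(frozen=True)
class DHGroup:
    """A prime-order multiplicative group ``(p, g)``."""

    p: int
    g: int

    def __post_init__(self) -> None:
        if self.p <= 3:
            raise KeyExchangeError(f"group prime must exceed 3, got {self.p}")
        if not 1 < self.g < self.p:
            raise KeyExchangeError(f"generator {self.g} outside (1, p)")


#: Hand-checkable toy group.
TOY_GROUP = DHGroup(p=23, g=5)

#: 64-bit safe prime (p = 2q + 1 with q prime); g = 2 generates the group.
DEFAULT_GROUP = DHGroup(p=18446744073709550147, g=2)


@dataclass(frozen=True)
class KeyPair:
    private_key: int
    public_key: int
    group: DHGroup


@dataclass
class MaskedUpdate:
    """A node's per-round submission: masked values + weight + digest."""

    node_id: int
    round: int
    masked_values: np.ndarray
    sample_count: int
    digest: str
    fixed_point: bool = True

    def verify_digest(self) -> bool:
        return _digest(self.masked_values) == self.digest


def _digest(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()


def generate_keypair(group: DHGroup, seed: int) -> KeyPair:
    """Deterministically draw a private key in ``[2, p - 2]``."""
    rng = np.random.default_rng([int(seed), group.p % (2**32)])
    # rejection-free: uniform over the valid range via Python ints
    span = group.p - 3
    private = 2 + int.from_bytes(rng.bytes(16), "big") % span
    return KeyPair(private, pow(group.g, private, group.p), group)


def derive_shared_seed(private_i: int, public_j: int, group: DHGroup) -> int:
    """Shared 64-bit seed: symmetric in the two parties.

    ``derive(a, g^b) == derive(b, g^a)`` because both equal
    ``hash(g^(ab) mod p)``.
    """
    if not 1 <= public_j <= group.p - 1:
        raise KeyExchangeError(
            f"public key {public_j} outside [1, {group.p - 1}]"
        )
    secret = pow(public_j, private_i, group.p)
    h = hashlib.sha256(secret.to_bytes((secret.bit_length() + 7) // 8 or 1, "big"))
    return int.from_bytes(h.digest()[:8], "big")


def _mask_vector(seed: int, n: int, fixed_point: bool) -> np.ndarray:
    rng = np.random.default_rng([int(seed)])
    if fixed_point:
        return rng.integers(-_MASK_BOUND, _MASK_BOUND, size=n, dtype=np.int64)
    return rng.normal(0.0, _FLOAT_MASK_SD, size=n)


def quantize(values: np.ndarray, scale: int = FIXED_POINT_SCALE) -> np.ndarray:
    return np.rint(np.asarray(values, dtype=np.float64) * scale).astype(np.int64)


def dequantize(values: np.ndarray, scale: int = FIXED_POINT_SCALE) -> np.ndarray:
    return np.asarray(values, dtype=np.float64) / scale


def mask_update(
    values: np.ndarray,
    node_id: int,
    pair_seeds: Mapping[int, int],
    round: int = 0,
    sample_count: int = 1,
    fixed_point: bool = True,
) -> MaskedUpdate:
    """Mask a plain vector with the node's pairwise antisymmetric masks.

    ``pair_seeds`` maps every *other* participant's id to the DH-derived
    shared seed; the per-round mask is drawn from ``(shared seed, round)``
    so masks never repeat across rounds.  With no pairs (a single node)
    the submission is the plain vector.
    """
    values = np.asarray(values, dtype=np.float64)
    if node_id in pair_seeds:
        raise MaskingError(f"pair_seeds must not include the node itself ({node_id})")
    out = quantize(values) if fixed_point else values.copy()
    for j, seed in sorted(pair_seeds.items()):
        m = _mask_vector(_round_seed(seed, round), values.size, fixed_point)
        if j > node_id:
            out = out + m
        else:
            out = out - m
    return MaskedUpdate(
        node_id=node_id,
        round=round,
        masked_values=out,
        sample_count=int(sample_count),
        digest=_digest(out),
        fixed_point=fixed_point,
    )


def _round_seed(shared_seed: int, round: int) -> int:
    h = hashlib.sha256(f"{shared_seed}:{round}".encode())
    return int.from_bytes(h.digest()[:8], "big")


def unmask_aggregate(
    updates: Sequence[MaskedUpdate], participants: Sequence[int] | None = None
) -> tuple[np.ndarray, int]:
    """Sum masked updates; pair masks cancel, leaving the plain sum.

    Returns ``(sum of plain parameter vectors, total sample count)``.

    Raises
    ------
    MissingParticipantError
        Naming the absent node(s), because without every declared
        participant the antisymmetric masks cannot cancel.
    """
    if not updates:
        raise MaskingError("no updates to aggregate")
    present = {u.node_id for u in updates}
    declared = set(participants) if participants is not None else present
    missing = sorted(declared - present)
    if missing:
        raise MissingParticipantError(
            f"missing update(s) from node(s) {missing}: masks cannot cancel"
        )
    fixed = updates[0].fixed_point
    if any(u.fixed_point != fixed for u in updates):
        raise MaskingError("mixed fixed-point and float updates")
    for u in updates:
        if not u.verify_digest():
            raise MaskingError(f"digest mismatch for node {u.node_id}")
    total = updates[0].masked_values.copy()
    for u in updates[1:]:
        if u.masked_values.size != total.size:
            raise MaskingError("updates have mismatched lengths")
        total = total + u.masked_values
    n = sum(u.sample_count for u in updates)
    return (dequantize(total) if fixed else total), n
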