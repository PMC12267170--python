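"""The round-based swarm-learning training loop, plus baselines.

Each round: a leader is elected deterministically from the ledger head
hash; every node trains one epoch (by default) on its local shard from the
current global parameters; sample-weighted updates are screened against a
robust distance rule, masked pairwise (Diffie-Hellman-seeded, antisymmetric,
cancelling in the sum), aggregated by Fed-Avg, committed to the hash-chained
ledger by quorum vote, broadcast back to all nodes, and scored on the
global validation set.  The best checkpoint is the round with the highest
validation accuracy (earliest on ties).

The public surface follows the modelling-object convention: build a
:class:`SwarmModel` from node shards and a validation set, call
``fit()``, and read estimates and diagnostics off the returned
:class:`SwarmResults`.  ``run_swarm`` / ``run_centralized`` are thin
functional wrappers.

Degenerate-protocol guarantees (tested):

* one node, masking off  ==  plain local training, bit-for-bit;
* masking on vs off in fixed-point mode gives identical aggregates every
  round (the pair masks cancel exactly);
* a single adversarial node submitting wildly scaled updates is screened
  out, leaving the aggregate of the honest nodes untouched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import secure
from .classifier import (
    ModelSpec,
    ParameterVector,
    TrainConfig,
    _as_xy,
    accuracy,
    init_model,
    predict_proba,
    train_local,
)
from .errors import ProtocolError, TrainingError
from .ledger import Ledger, commit_round, verify_chain
from .secure import DEFAULT_GROUP, DHGroup


@dataclass
class SwarmConfig:
    """Protocol settings for one collaborative run."""

    n_rounds: int = 100
    epochs_per_round: int = 1
    min_participation: int = 3
    screening_factor: float = 5.0
    masking: bool = True
    fixed_point: bool = True
    seed: int = 0
    group: DHGroup = DEFAULT_GROUP

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.min_participation < 1:
            raise ProtocolError("n_rounds and min_participation must be >= 1")
        if self.screening_factor <= 0:
            raise ProtocolError("screening_factor must be positive")


@dataclass
class RoundResult:
    round: int
    leader_id: int
    kept: list[int]
    rejected: list[int]
    params: ParameterVector
    metrics: dict[str, float]


def elect_leader(head_hash: str, round: int, node_ids: Sequence[int]) -> int:
    """Deterministic, ledger-seeded uniform leader election.

    Every node can recompute the same choice from the public chain head:
    the PRNG is seeded by ``hash(head || round || sorted ids)``.
    """
    ids = sorted(node_ids)
    if not ids:
        raise ProtocolError("cannot elect a leader from an empty node set")
    h = hashlib.sha256(
        f"{head_hash}|{round}|{','.join(map(str, ids))}".encode()
    ).digest()
    rng = np.random.default_rng(int.from_bytes(h[:8], "big"))
    return ids[int(rng.integers(len(ids)))]


def fedavg(updates: Sequence[tuple[np.ndarray, int]]) -> np.ndarray:
    """Sample-weighted federated average: sum_i n_i w_i / sum_i n_i.

    A convex combination — every coordinate lies within the input range.
    A single update is returned unchanged (exactly).
    """
    if not updates:
        raise TrainingError("fedavg needs at least one update")
    lengths = {np.asarray(v).size for v, _ in updates}
    if len(lengths) != 1:
        raise TrainingError(f"update length mismatch: {sorted(lengths)}")
    total = sum(int(n) for _, n in updates)
    if total <= 0:
        raise TrainingError("zero total sample count")
    if len(updates) == 1:
        return np.asarray(updates[0][0], dtype=np.float64).copy()
    acc = np.zeros(lengths.pop())
    for v, n in updates:
        acc = acc + np.asarray(v, dtype=np.float64) * (n / total)
    return acc


def screen_updates(
    vectors: Sequence[np.ndarray], screening_factor: float = 5.0
) -> tuple[list[int], list[int]]:
    """Threshold-based poisoning screen.

    Rejects update ``u`` iff ``||u - med||_2 > factor * median_j ||u_j -
    med||_2`` where ``med`` is the coordinate-wise median vector.  With two
    or fewer updates nothing is rejected (no robust centre exists).

    Returns ``(kept indices, rejected indices)``.
    """
    if not vectors:
        raise TrainingError("nothing to screen")
    if len(vectors) <= 2:
        return list(range(len(vectors))), []
    stack = np.stack([np.asarray(v, dtype=np.float64) for v in vectors])
    med = np.median(stack, axis=0)
    dists = np.linalg.norm(stack - med, axis=1)
    threshold = screening_factor * float(np.median(dists))
    kept = [i for i, d in enumerate(dists) if d <= threshold]
    rejected = [i for i, d in enumerate(dists) if d > threshold]
    return kept, rejected


class SwarmModel:
    """A swarm-learning run specified by node shards and a validation set.

    Parameters
    ----------
    shards : sequence
        One training shard per node (manifest, record list, or ``(X, y)``).
    val : data
        Global validation set used for per-round scoring and
        best-checkpoint selection.
    model_spec, train_config, config
        Learner architecture, local-training hyperparameters, and protocol
        settings.
    adversaries : mapping, optional
        ``node_id -> scale``; those nodes multiply their parameter update
        by ``scale`` before submission (poisoning simulation).
    """

    def __init__(
        self,
        shards: Sequence,
        val,
        model_spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
        config: SwarmConfig | None = None,
        adversaries: dict[int, float] | None = None,
        eval_fn: Callable[[ParameterVector], dict[str, float]] | None = None,
    ):
        if not shards:
            raise ProtocolError("need at least one shard")
        self.spec = model_spec or ModelSpec()
        self.train_config = train_config or TrainConfig()
        self.config = config or SwarmConfig()
        if len(shards) < self.config.min_participation:
            raise ProtocolError(
                f"{len(shards)} nodes below minimum participation "
                f"{self.config.min_participation}"
            )
        self.node_ids = list(range(1, len(shards) + 1))
        # features are extracted once per shard; record order is normalised
        self.shards = {
            nid: _as_xy(self.spec, shard) for nid, shard in zip(self.node_ids, shards)
        }
        for nid, (X, y) in self.shards.items():
            if len(y) == 0:
                raise ProtocolError(f"node {nid} has an empty shard")
        self.val = _as_xy(self.spec, val)
        self.adversaries = dict(adversaries or {})
        self.eval_fn = eval_fn

    # -- protocol pieces -------------------------------------------------

    def _pair_seeds(self) -> dict[int, dict[int, int]]:
        """DH exchange: every pair agrees on a shared mask seed."""
        keys = {
            nid: secure.generate_keypair(
                self.config.group, secure._round_seed(self.config.seed, nid)
            )
            for nid in self.node_ids
        }
        out: dict[int, dict[int, int]] = {nid: {} for nid in self.node_ids}
        for i in self.node_ids:
            for j in self.node_ids:
                if i < j:
                    s = secure.derive_shared_seed(
                        keys[i].private_key, keys[j].public_key, self.config.group
                    )
                    # symmetry: node j derives the identical seed
                    assert s == secure.derive_shared_seed(
                        keys[j].private_key, keys[i].public_key, self.config.group
                    )
                    out[i][j] = s
                    out[j][i] = s
        return out

    def _evaluate(self, params: ParameterVector) -> dict[str, float]:
        if self.eval_fn is not None:
            return self.eval_fn(params)
        return {"val_accuracy": accuracy(params, self.val, self.spec)}

    def _aggregate(
        self, round_idx: int, kept_ids: list[int], updates: dict[int, np.ndarray]
    ) -> np.ndarray:
        counts = {nid: len(self.shards[nid][1]) for nid in kept_ids}
        total = sum(counts.values())
        if self.config.masking:
            pair_seeds = self._pair_seeds()
            masked = []
            for nid in kept_ids:
                seeds = {j: pair_seeds[nid][j] for j in kept_ids if j != nid}
                masked.append(
                    secure.mask_update(
                        updates[nid] * counts[nid],
                        nid,
                        seeds,
                        round=round_idx,
                        sample_count=counts[nid],
                        fixed_point=self.config.fixed_point,
                    )
                )
            summed, n = secure.unmask_aggregate(masked, kept_ids)
            return summed / n
        if self.config.fixed_point:
            # same quantization path as masking, so fixed-point trajectories
            # are identical with masks on or off
            summed = np.zeros(next(iter(updates.values())).size)
            for nid in kept_ids:
                summed = summed + secure.dequantize(
                    secure.quantize(updates[nid] * counts[nid])
                )
            return summed / total
        return fedavg([(updates[nid], counts[nid]) for nid in kept_ids])

    # -- the loop --------------------------------------------------------

    def fit(self) -> "SwarmResults":
        cfg = self.config
        ledger = Ledger(nodes=self.node_ids)
        params = init_model(self.spec, cfg.seed)
        history: list[RoundResult] = []
        best: tuple[float, int, ParameterVector] | None = None

        for r in range(cfg.n_rounds):
            leader = elect_leader(ledger.head_hash, r, self.node_ids)
            updates: dict[int, np.ndarray] = {}
            for nid in self.node_ids:
                trained, _ = train_local(
                    params,
                    self.shards[nid],
                    self.train_config,
                    self.spec,
                    epoch_offset=r * self.train_config.epochs_per_round,
                    node_salt=nid,
                )
                vec = trained.values
                if nid in self.adversaries:
                    vec = vec * self.adversaries[nid]
                updates[nid] = vec

            kept_idx, rejected_idx = screen_updates(
                [updates[nid] for nid in self.node_ids], cfg.screening_factor
            )
            kept_ids = [self.node_ids[i] for i in kept_idx]
            rejected_ids = [self.node_ids[i] for i in rejected_idx]
            if len(kept_ids) < cfg.min_participation:
                raise ProtocolError(
                    f"round {r}: {len(kept_ids)} updates kept, below minimum "
                    f"participation {cfg.min_participation}"
                )

            aggregate = self._aggregate(r, kept_ids, updates)
            params = ParameterVector(aggregate, params.shape_descriptor)
            metrics = self._evaluate(params)

            digest = hashlib.sha256(aggregate.tobytes()).hexdigest()
            payload = {
                "round": r,
                "leader": leader,
                "participants": self.node_ids,
                "kept": kept_ids,
                "rejected": rejected_ids,
                "aggregate_digest": digest,
                "metrics": {k: round(float(v), 10) for k, v in metrics.items()},
                "votes": {str(nid): True for nid in kept_ids},
            }
            committed = commit_round(
                {nid: True for nid in kept_ids}, self.node_ids
            )
            if not committed:  # retry once, then abort
                committed = commit_round(
                    {nid: True for nid in kept_ids}, self.node_ids
                )
                if not committed:
                    raise ProtocolError(f"round {r}: quorum commit failed twice")
            ledger.append_block(payload)

            history.append(
                RoundResult(r, leader, kept_ids, rejected_ids, params.copy(), metrics)
            )
            score = metrics.get("val_accuracy", next(iter(metrics.values())))
            if best is None or score > best[0]:
                best = (score, r, params.copy())

        return SwarmResults(
            model=self,
            history=history,
            best_params=best[2],
            best_round=best[1],
            best_score=best[0],
            ledger=ledger,
        )


@dataclass
class SwarmResults:
    """Fitted swarm run: per-round history, best checkpoint, audit chain."""

    model: SwarmModel
    history: list[RoundResult]
    best_params: ParameterVector
    best_round: int
    best_score: float
    ledger: Ledger

    @property
    def final_params(self) -> ParameterVector:
        return self.history[-1].params

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.history:
            row = {"round": h.round, "leader": h.leader_id, "n_kept": len(h.kept)}
            row.update(h.metrics)
            rows.append(row)
        return pd.DataFrame(rows)

    def predict_proba(self, data) -> np.ndarray:
        return predict_proba(self.best_params, data, self.model.spec)

    def accuracy(self, data) -> float:
        return accuracy(self.best_params, data, self.model.spec)

    def verify_ledger(self) -> bool:
        ok, _ = verify_chain(self.ledger)
        return ok

    def summary(self) -> str:
        frame = self.metrics_frame()
        lines = [
            "Swarm learning run",
            "==================",
            f"nodes:            {len(self.model.node_ids)}",
            f"rounds:           {len(self.history)}",
            f"masking:          {'on' if self.model.config.masking else 'off'}"
            f" ({'fixed-point' if self.model.config.fixed_point else 'float'})",
            f"best round:       {self.best_round}"
            f"  (val accuracy {self.best_score:.4f})",
            f"final val acc:    {frame.iloc[-1].get('val_accuracy', float('nan')):.4f}",
            f"rounds w/ reject: {int((frame['n_kept'] < len(self.model.node_ids)).sum())}",
            f"ledger verified:  {self.verify_ledger()}",
        ]
        return "\n".join(lines)


# -- baselines -----------------------------------------------------------


@dataclass
class CentralResults:
    """Single-site (centralized or local-only) training result."""

    best_params: ParameterVector
    best_epoch: int
    best_score: float
    trace: pd.DataFrame
    spec: ModelSpec

    def accuracy(self, data) -> float:
        return accuracy(self.best_params, data, self.spec)

    def predict_proba(self, data) -> np.ndarray:
        return predict_proba(self.best_params, data, self.spec)


def run_centralized(
    train_data,
    val,
    model_spec: ModelSpec | None = None,
    train_config: TrainConfig | None = None,
    epochs: int = 100,
    node_salt: int = 1,
) -> CentralResults:
    """Single-site training with per-epoch best-checkpoint selection.

    With the same seed, salt and data, this trajectory is bit-identical to
    a one-node swarm with masking off — the protocol-collapse property.
    """
    spec = model_spec or ModelSpec()
    cfg = train_config or TrainConfig()
    X, y = _as_xy(spec, train_data)
    if len(y) == 0:
        raise TrainingError("cannot train on an empty manifest")
    params = init_model(spec, cfg.seed)
    best: tuple[float, int, ParameterVector] | None = None
    rows = []
    step = TrainConfig(
        epochs_per_round=1,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
        seed=cfg.seed,
    )
    Xv, yv = _as_xy(spec, val)
    for e in range(epochs):
        params, losses = train_local(
            params, (X, y), step, spec, epoch_offset=e, node_salt=node_salt
        )
        score = accuracy(params, (Xv, yv), spec)
        rows.append({"epoch": e, "loss": losses[0], "val_accuracy": score})
        if best is None or score > best[0]:
            best = (score, e, params.copy())
    return CentralResults(
        best_params=best[2],
        best_epoch=best[1],
        best_score=best[0],
        trace=pd.DataFrame(rows),
        spec=spec,
    )


def run_swarm(
    shards: Sequence,
    config: SwarmConfig,
    global_val,
    model_spec: ModelSpec | None = None,
    train_config: TrainConfig | None = None,
    **kwargs,
) -> SwarmResults:
    """Functional wrapper over :class:`SwarmModel`."""
    return SwarmModel(
        shards, global_val, model_spec, train_config, config, **kwargs
    ).fit()
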