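"""The per-node learner: a tiny deterministic reference classifier.

The swarm protocol only needs a *contract* — get/set a flat parameter
vector, train locally for a given number of epochs, and emit per-class
probabilities.  The reference implementation is multinomial logistic
regression on block-pooled, mean/scale-normalized pixels, trained with
minibatch SGD plus momentum and weight decay.  It is deliberately tiny
(~1.5k parameters at the 64 x 64 default) so that hundred-round swarm runs
finish on one CPU, while still separating the synthetic six-class images
cleanly.

Determinism: parameter initialisation derives from ``(spec, seed)``; the
shuffle of epoch ``t`` derives from ``(config.seed, node_salt, t)`` and is
independent of manifest file order (records are sorted by id first).
Momentum buffers reset at every epoch boundary, so training ``E`` epochs in
one call is bit-identical to ``E`` chained single-epoch calls — the
property that makes one swarm round per epoch exactly composable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import TrainingError
from .synth import CLASSES, CohortManifest

_REGISTRY = ("softmax_pool",)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for the registered reference model."""

    name: str = "softmax_pool"
    input_shape: tuple[int, int] = (64, 64)
    pool: int = 4
    n_classes: int = len(CLASSES)
    norm_mean: float = 0.485
    norm_std: float = 0.229

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise TrainingError(
                f"unknown architecture {self.name!r}; registered: {_REGISTRY}"
            )

    @property
    def n_features(self) -> int:
        h, w = self.input_shape
        return (h // self.pool) * (w // self.pool)

    @property
    def shape_descriptor(self) -> list[tuple[str, tuple[int, ...]]]:
        return [
            ("weights", (self.n_features, self.n_classes)),
            ("bias", (self.n_classes,)),
        ]


@dataclass
class ParameterVector:
    """Flat float64 parameter vector plus its shape descriptor."""

    values: np.ndarray
    shape_descriptor: list[tuple[str, tuple[int, ...]]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        total = sum(int(np.prod(s)) for _, s in self.shape_descriptor)
        if total != self.values.size:
            raise TrainingError(
                f"vector length {self.values.size} != descriptor total {total}"
            )
        if not np.all(np.isfinite(self.values)):
            raise TrainingError("parameter vector contains non-finite entries")

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.values.copy(), list(self.shape_descriptor))

    def unpack(self) -> dict[str, np.ndarray]:
        out, offset = {}, 0
        for name, shape in self.shape_descriptor:
            n = int(np.prod(shape))
            out[name] = self.values[offset : offset + n].reshape(shape)
            offset += n
        return out

    @classmethod
    def pack(cls, arrays: dict[str, np.ndarray], descriptor) -> "ParameterVector":
        flat = np.concatenate([np.asarray(arrays[n], dtype=np.float64).ravel() for n, _ in descriptor])
        return cls(flat, list(descriptor))

    def save(self, path: str | Path) -> None:
        """Write the flat vector (binary .npy) plus a JSON descriptor."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        path.with_suffix(".json").write_text(
            json.dumps([[n, list(s)] for n, s in self.shape_descriptor]) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ParameterVector":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        desc = [
            (n, tuple(s)) for n, s in json.loads(path.with_suffix(".json").read_text())
        ]
        return cls(values, desc)


@dataclass
class TrainConfig:
    """Local-training hyperparameters (one epoch per swarm round)."""

    epochs_per_round: int = 1
    batch_size: int = 16
    learning_rate: float = 0.02
    momentum: float = 0.937
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_per_round < 0 or self.batch_size < 1:
            raise TrainingError("epochs_per_round must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be positive")


def extract_features(spec: ModelSpec, images: Sequence[np.ndarray]) -> np.ndarray:
    """Block-pool and normalize raw images into the model's feature space."""
    k = spec.pool
    rows = []
    for img in images:
        h, w = img.shape
        pooled = img.reshape(h // k, k, w // k, k).mean(axis=(1, 3)).ravel()
        rows.append((pooled - spec.norm_mean) / spec.norm_std)
    return np.asarray(rows)


def _as_xy(spec: ModelSpec, data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a manifest, a record list, or a prebuilt (X, y) pair."""
    if isinstance(data, tuple) and len(data) == 2:
        return np.asarray(data[0]), np.asarray(data[1])
    records = list(data.records if isinstance(data, CohortManifest) else data)
    records.sort(key=lambda r: r.id)  # order-independence of manifest files
    X = extract_features(spec, [r.pixels for r in records])
    y = np.array([CLASSES.index(r.label) for r in records])
    return X, y


def init_model(spec: ModelSpec, seed: int) -> ParameterVector:
    """Deterministic parameter initialisation: N(0, 0.01) weights, zero bias."""
    rng = np.random.default_rng([int(seed), 7919])
    W = rng.normal(0.0, 0.01, (spec.n_features, spec.n_classes))
    b = np.zeros(spec.n_classes)
    return ParameterVector.pack({"weights": W, "bias": b}, spec.shape_descriptor)


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    return P / P.sum(axis=1, keepdims=True)


def train_local(
    params: ParameterVector,
    shard,
    config: TrainConfig,
    spec: ModelSpec | None = None,
    epoch_offset: int = 0,
    node_salt: int = 0,
) -> tuple[ParameterVector, list[float]]:
    """Run ``config.epochs_per_round`` epochs of minibatch SGD on a shard.

    Parameters
    ----------
    shard
        A :class:`~slsim.synth.CohortManifest`, list of records, or an
        ``(X, y)`` feature pair.
    epoch_offset
        Global epoch index of the first epoch; the shuffle of epoch ``t``
        is seeded by ``(config.seed, node_salt, epoch_offset + t)`` so a
        swarm round ``r`` continues the same shuffle stream that an
        uninterrupted local run would use.

    Returns the updated parameters and the mean cross-entropy per epoch.
    """
    spec = spec or ModelSpec()
    X, y = _as_xy(spec, shard)
    if len(y) == 0:
        raise TrainingError("cannot train on an empty shard")
    if config.epochs_per_round == 0:
        return params.copy(), []

    arrs = params.copy().unpack()
    W, b = arrs["weights"], arrs["bias"]
    lr, mom, wd, bs = (
        config.learning_rate,
        config.momentum,
        config.weight_decay,
        config.batch_size,
    )
    losses = []
    for e in range(config.epochs_per_round):
        rng = np.random.default_rng([config.seed, node_salt, epoch_offset + e])
        order = rng.permutation(len(y))
        vW = np.zeros_like(W)
        vb = np.zeros_like(b)
        epoch_loss = 0.0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            Xb, yb = X[idx], y[idx]
            P = _softmax(Xb @ W + b)
            Y = np.zeros_like(P)
            Y[np.arange(len(idx)), yb] = 1.0
            epoch_loss += -np.log(np.maximum(P[np.arange(len(idx)), yb], 1e-12)).sum()
            G = Xb.T @ (P - Y) / len(idx) + wd * W
            gb = (P - Y).mean(axis=0)
            vW = mom * vW - lr * G
            vb = mom * vb - lr * gb
            W = W + vW
            b = b + vb
        losses.append(epoch_loss / len(y))
    out = ParameterVector.pack({"weights": W, "bias": b}, spec.shape_descriptor)
    return out, losses


def predict_proba(params: ParameterVector, data, spec: ModelSpec | None = None) -> np.ndarray:
    """Per-image class probabilities; each row sums to 1."""
    spec = spec or ModelSpec()
    if isinstance(data, tuple):
        X = np.asarray(data[0])
    elif isinstance(data, np.ndarray) and data.ndim == 2:
        X = data
    else:
        records = list(data.records if isinstance(data, CohortManifest) else data)
        records.sort(key=lambda r: r.id)  # same canonical order as training
        X = extract_features(spec, [r.pixels for r in records])
    if X.shape[1] != spec.n_features:
        raise TrainingError(
            f"feature dimension {X.shape[1]} != model's {spec.n_features}"
        )
    arrs = params.unpack()
    return _softmax(X @ arrs["weights"] + arrs["bias"])


def accuracy(params: ParameterVector, data, spec: ModelSpec | None = None) -> float:
    """Top-1 accuracy on a manifest, record list, or (X, y) pair."""
    spec = spec or ModelSpec()
    X, y = _as_xy(spec, data)
    pred = predict_proba(params, (X, None), spec).argmax(axis=1)
    return float((pred == y).mean())
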