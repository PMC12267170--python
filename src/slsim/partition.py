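"""Cohort partitioning: train/val/test splitting and three-node sharding.

Implements the study's data setup: an 8:1:1 stratified train/validation/test
split, and a 5:3:2 apportionment of the training pool across three hospital
nodes, either *balanced* (per-class stratified, IID) or *unbalanced* (each
fracture class exclusive to one node, controls split 907:325:410 — the
non-IID regime of the node-distribution table).

Integer apportionment uses the largest-remainder (Hamilton) rule with ties
broken toward the lower part index; applied to a 3,026-image pool with
ratios 5:3:2 this reproduces the printed node totals (1,513 / 908 / 605).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .errors import PartitionError

if TYPE_CHECKING:  # pragma: no cover
    from .synth import CohortManifest


@dataclass
class PartitionSpec:
    """How to split a cohort and shard its training part across nodes."""

    split_ratios: tuple[float, float, float] = (8, 1, 1)
    node_ratios: Sequence[float] = (5, 3, 2)
    mode: str = "balanced"
    seed: int = 0
    #: If False, node sharding apportions the pool globally rather than
    #: per class (the per-class stratified default keeps shards IID).
    stratify_nodes: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("balanced", "unbalanced"):
            raise PartitionError(f"unknown mode {self.mode!r}")
        if any(r <= 0 for r in self.split_ratios) or any(r <= 0 for r in self.node_ratios):
            raise PartitionError("all ratios must be strictly positive")


def apportion(total: int, ratios: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items over ``ratios``.

    Each part first receives the floor of its exact quota
    ``total * r_i / sum(r)``; remaining items go to the parts with the
    largest fractional remainders, ties broken toward the lower index.

    >>> apportion(3026, [5, 3, 2]).tolist()
    [1513, 908, 605]
    """
    if total < 0:
        raise PartitionError(f"total must be non-negative, got {total}")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim != 1 or len(ratios) == 0 or np.any(ratios <= 0):
        raise PartitionError("ratios must be a non-empty sequence of positive weights")
    quota = ratios * (total / ratios.sum())
    sizes = np.floor(quota).astype(int)
    remainder = int(total - sizes.sum())
    if remainder:
        order = np.argsort(-(quota - sizes), kind="stable")  # stable => lower index wins ties
        sizes[order[:remainder]] += 1
    return sizes


def _stratified_assign(
    manifest: "CohortManifest", ratios: Sequence[float], seed: int, salt: int
) -> list[list[int]]:
    """Per-class largest-remainder assignment of record indices to parts."""
    from .synth import CLASSES

    parts: list[list[int]] = [[] for _ in ratios]
    for ci, label in enumerate(CLASSES):
        idx = manifest.by_label(label)
        if not idx:
            continue
        rng = np.random.default_rng([seed, salt, ci])
        perm = rng.permutation(len(idx))
        sizes = apportion(len(idx), ratios)
        offset = 0
        for p, n in enumerate(sizes):
            parts[p].extend(idx[perm[j]] for j in range(offset, offset + n))
            offset += n
    return parts


def split_train_val_test(
    manifest: "CohortManifest", spec: PartitionSpec
) -> tuple["CohortManifest", "CohortManifest", "CohortManifest"]:
    """Stratified 8:1:1 (by default) split of a cohort.

    The three outputs are pairwise disjoint, their union is the input, and
    per-class sizes follow :func:`apportion`.  Deterministic under
    ``spec.seed``.
    """
    if len(manifest) == 0:
        raise PartitionError("cannot split an empty manifest")
    parts = _stratified_assign(manifest, spec.split_ratios, spec.seed, salt=1)
    out = []
    for tag, idx in zip(("train", "val", "test"), parts):
        sub = manifest.subset(sorted(idx))
        for r in sub.records:
            r.cohort = tag
        out.append(sub)
    return tuple(out)  # type: ignore[return-value]


def make_node_shards(
    train_manifest: "CohortManifest",
    spec: PartitionSpec,
    class_node_counts: Mapping[str, Sequence[int]] | None = None,
) -> list["CohortManifest"]:
    """Apportion a training pool across nodes.

    ``balanced``: per-class stratified largest-remainder split by
    ``spec.node_ratios`` (IID shards); with ``stratify_nodes=False`` the
    pool is apportioned globally instead.

    ``unbalanced``: the study's non-IID regime — three nodes, every
    fracture class exclusively on one node (C,D -> node 1; B,K -> node 2;
    A -> node 3) and controls split in the printed 907:325:410 proportion.

    ``class_node_counts`` overrides the per-class node sizes with explicit
    counts (class -> one count per node), which is how the published node
    table — a random sample, not an exact proportional split — is
    reproduced cell by cell.

    Shards are pairwise disjoint and their union is the input.
    """
    from .synth import CLASSES
    from .tables import UNBALANCED_CLASS_NODE, UNBALANCED_NEG_SPLIT

    if class_node_counts is not None:
        parts: list[list[int]] = [[] for _ in range(len(next(iter(class_node_counts.values()))))]
        for ci, label in enumerate(CLASSES):
            idx = train_manifest.by_label(label)
            if not idx:
                continue
            counts = list(class_node_counts.get(label, []))
            if sum(counts) != len(idx):
                raise PartitionError(
                    f"class {label}: counts {counts} do not sum to pool size {len(idx)}"
                )
            rng = np.random.default_rng([spec.seed, 2, ci])
            perm = rng.permutation(len(idx))
            offset = 0
            for p, n in enumerate(counts):
                parts[p].extend(idx[perm[j]] for j in range(offset, offset + n))
                offset += n
    elif spec.mode == "balanced":
        if spec.stratify_nodes:
            parts = _stratified_assign(train_manifest, spec.node_ratios, spec.seed, salt=2)
        else:
            rng = np.random.default_rng([spec.seed, 2])
            perm = rng.permutation(len(train_manifest))
            sizes = apportion(len(train_manifest), spec.node_ratios)
            parts, offset = [], 0
            for n in sizes:
                parts.append([int(perm[j]) for j in range(offset, offset + n)])
                offset += n
    else:
        if len(spec.node_ratios) != 3:
            raise PartitionError("unbalanced mode is defined for exactly 3 nodes")
        parts = [[], [], []]
        for ci, label in enumerate(CLASSES):
            idx = train_manifest.by_label(label)
            if not idx:
                continue
            if label == "NEG":
                rng = np.random.default_rng([spec.seed, 2, ci])
                perm = rng.permutation(len(idx))
                sizes = apportion(len(idx), UNBALANCED_NEG_SPLIT)
                offset = 0
                for p, n in enumerate(sizes):
                    parts[p].extend(idx[perm[j]] for j in range(offset, offset + n))
                    offset += n
            else:
                parts[UNBALANCED_CLASS_NODE[label]].extend(idx)

    shards = []
    for p, idx in enumerate(parts):
        sub = train_manifest.subset(sorted(idx))
        for r in sub.records:
            r.node = p + 1
        shards.append(sub)
    return shards
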