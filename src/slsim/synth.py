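"""Synthetic knee-radiograph generator.

Produces seeded, separable six-class grayscale images standing in for the
clinical X-ray cohorts, so that every downstream stage (partitioning,
training, secure aggregation, evaluation) can be exercised without any
patient data.

Classes follow the Schatzker-derived scheme used throughout the package:

====== =========================================
label  meaning
====== =========================================
A      Schatzker I
B      Schatzker II and III
C      Schatzker IV
D      Schatzker V and VI
K      intercondylar ridge fracture
NEG    no tibial-plateau fracture (control)
====== =========================================

Each fracture class is rendered as one dark oriented line segment (a crude
"fracture line") on a smooth noisy background.  The five fracture classes
occupy disjoint orientation bands 36 degrees apart, which guarantees that a
small linear classifier can separate them — the generator aims for
learnability at desk scale, not radiological realism.  ``NEG`` images carry
no lesion primitive at all.

Determinism contract: identical ``(label, seed, size)`` always yields
bit-identical pixels, and cohort generation derives one RNG stream per
``(master seed, class, index)`` so changing one class count never reshuffles
the images of another class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ImageSizeError, PartitionError, UnknownLabelError

#: The six image classes, in canonical order.
CLASSES: tuple[str, ...] = ("A", "B", "C", "D", "K", "NEG")

#: The five fracture (lesion-bearing) classes.
FRACTURE_CLASSES: tuple[str, ...] = ("A", "B", "C", "D", "K")

#: Centre of the orientation band of each fracture class, degrees.
LESION_ANGLES: dict[str, float] = {"A": 0.0, "B": 36.0, "C": 72.0, "D": 108.0, "K": 144.0}

#: Half-width of each class's orientation band, degrees.  Bands are 36 deg
#: apart so +-8 deg of jitter keeps them disjoint with margin.
ANGLE_JITTER = 8.0

#: Minimum supported image edge.
MIN_SIZE = 32

_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}

COHORT_TAGS = ("train", "val", "test", "external")


@dataclass
class ImageRecord:
    """One labelled synthetic radiograph.

    Attributes
    ----------
    id : str
        Unique identifier within a manifest.
    pixels : ndarray
        ``H x W`` float array of intensities in ``[0, 1]``.
    label : str
        One of :data:`CLASSES`.
    cohort : str
        Cohort tag (``train``/``val``/``test``/``external``).
    node : int or None
        1-based node assignment, if sharded.
    lesion_mask : ndarray
        Boolean mask of the lesion primitive; empty for ``NEG``.
    """

    id: str
    pixels: np.ndarray
    label: str
    cohort: str = "train"
    node: int | None = None
    lesion_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lesion_mask is None:
            self.lesion_mask = np.zeros(self.pixels.shape, dtype=bool)


class CohortManifest:
    """An ordered collection of :class:`ImageRecord` with unique ids."""

    def __init__(self, records: Sequence[ImageRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise PartitionError("manifest ids must be unique")
        self.records: list[ImageRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def composition(self) -> dict[str, int]:
        """Per-class counts, equal to the multiset of record labels."""
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out

    def subset(self, indices: Iterable[int]) -> "CohortManifest":
        return CohortManifest([self.records[i] for i in indices])

    def by_label(self, label: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "label": [r.label for r in self.records],
                "cohort": [r.cohort for r in self.records],
                "node": [r.node if r.node is not None else "" for r in self.records],
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_json(self, path: str | Path) -> None:
        rows = self.to_frame().to_dict(orient="records")
        Path(path).write_text(json.dumps(rows, indent=1) + "\n")

    def save_images(self, directory: str | Path, fmt: str = "png") -> list[Path]:
        """Write every image as 8-bit grayscale PNG (lossless) or JPEG."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for r in self.records:
            arr = np.clip(np.rint(r.pixels * 255.0), 0, 255).astype(np.uint8)
            p = directory / f"{r.id}.{fmt}"
            Image.fromarray(arr, mode="L").save(p)
            paths.append(p)
        return paths


def generate_image(label: str, seed: int, size: tuple[int, int] = (64, 64)) -> ImageRecord:
    """Render one synthetic radiograph.

    The background is a tilted intensity gradient plus Gaussian noise; a
    fracture class then subtracts a dark line segment whose orientation is
    drawn from the class's (disjoint) angle band, with jittered centre,
    width and length.  ``NEG`` renders background only.

    Raises
    ------
    UnknownLabelError
        If ``label`` is not one of :data:`CLASSES`.
    ImageSizeError
        If either dimension is below 32.
    """
    if label not in _CLASS_CODE:
        raise UnknownLabelError(f"unknown class label {label!r}; expected one of {CLASSES}")
    h, w = int(size[0]), int(size[1])
    if h < MIN_SIZE or w < MIN_SIZE:
        raise ImageSizeError(f"image size {h}x{w} below minimum {MIN_SIZE}x{MIN_SIZE}")

    rng = np.random.default_rng([int(seed), _CLASS_CODE[label]])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    gx, gy = rng.uniform(-0.1, 0.1, 2)
    img = 0.55 + gx * (xx / w - 0.5) + gy * (yy / h - 0.5)
    img += rng.normal(0.0, 0.15, (h, w))

    mask = np.zeros((h, w), dtype=bool)
    if label != "NEG":
        ang = np.deg2rad(LESION_ANGLES[label] + rng.uniform(-ANGLE_JITTER, ANGLE_JITTER))
        cy = h / 2.0 + rng.uniform(-0.1, 0.1) * h
        cx = w / 2.0 + rng.uniform(-0.1, 0.1) * w
        width = rng.uniform(1.5, 2.5)
        half_len = rng.uniform(0.55, 0.8) * min(h, w) / 2.0
        dy, dx = np.sin(ang), np.cos(ang)
        py, px = yy - cy, xx - cx
        along = py * dy + px * dx
        across = np.abs(-py * dx + px * dy)
        mask = (np.abs(along) <= half_len) & (across <= width)
        img[mask] -= 0.45

    pixels = np.clip(img, 0.0, 1.0)
    return ImageRecord(
        id=f"{label}-{seed}", pixels=pixels, label=label, lesion_mask=mask
    )


def _record_seed(master_seed: int, label: str, index: int) -> int:
    """Independent per-image seed stream for (master seed, class, index)."""
    ss = np.random.SeedSequence([int(master_seed), _CLASS_CODE[label], int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)  # keep positive


def generate_cohort(
    composition: Mapping[str, int],
    cohort: str = "train",
    seed: int = 0,
    size: tuple[int, int] = (64, 64),
) -> CohortManifest:
    """Generate a full cohort matching ``composition`` exactly.

    Parameters
    ----------
    composition : mapping
        Per-class image counts; classes absent from the mapping get 0.
    cohort : str
        Tag stamped on every record.
    seed : int
        Master seed; per-image seeds derive from ``(seed, class, index)``.

    Raises
    ------
    PartitionError
        If any count is negative.
    UnknownLabelError
        If the composition names an unknown class.
    """
    records: list[ImageRecord] = []
    for label in CLASSES:
        n = int(composition.get(label, 0))
        if n < 0:
            raise PartitionError(f"negative count {n} for class {label}")
        for i in range(n):
            rec = generate_image(label, _record_seed(seed, label, i), size)
            rec.id = f"{cohort}-{label}-{i:05d}"
            rec.cohort = cohort
            records.append(rec)
    extra = set(composition) - set(CLASSES)
    if extra:
        raise UnknownLabelError(f"unknown classes in composition: {sorted(extra)}")
    return CohortManifest(records)
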