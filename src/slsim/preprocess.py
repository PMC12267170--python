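"""Deterministic image geometry and seeded classical augmentation.

The geometry chain mirrors the study's preprocessing: resize so the longer
edge is 608 px (aspect ratio preserved, bilinear), letterbox-pad to a square
canvas, and/or crop a region of interest and resize it to 480 x 480.
Augmentation is the classical set: random rotation within +-15 degrees,
horizontal flip with probability 0.5, a +-10 % multiplicative intensity
shift (the grayscale reinterpretation of an HSV shift), and mixup with
probability 0.15.  A 2 x 2 mosaic paste is available but off by default —
it targets detection training, not classification.

Pixel coordinates are 0-based, boxes half-open; letterbox padding puts the
extra pixel of an odd gap on the bottom/right.  All randomness flows from
``(AugmentConfig.seed, draw_seed)``, so any draw is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import PreprocessError

#: Channel-wise normalization constants (ImageNet convention); grayscale
#: pipelines use the first channel only.
NORM_MEAN = (0.485, 0.456, 0.406)
NORM_STD = (0.229, 0.224, 0.225)


@dataclass
class PreprocessConfig:
    long_side: int = 608
    roi_size: int = 480
    pad_value: float = 0.0
    mean: float = NORM_MEAN[0]
    std: float = NORM_STD[0]

    def __post_init__(self) -> None:
        if self.long_side < 1 or self.roi_size < 1:
            raise PreprocessError("sizes must be >= 1")
        if not 0.0 <= self.pad_value <= 1.0:
            raise PreprocessError("pad_value must lie in [0, 1]")


@dataclass
class AugmentConfig:
    rotation_limit: float = 15.0
    hflip_prob: float = 0.5
    intensity_shift: float = 0.10
    mixup_prob: float = 0.15
    mixup_alpha: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.mixup_prob):
            if not 0.0 <= p <= 1.0:
                raise PreprocessError("probabilities must lie in [0, 1]")
        if self.rotation_limit < 0:
            raise PreprocessError("rotation_limit must be >= 0")


def _bilinear_resize(image: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    pil = Image.fromarray(image.astype(np.float32), mode="F")
    out = pil.resize((out_hw[1], out_hw[0]), resample=Image.BILINEAR)
    return np.asarray(out, dtype=np.float64)


def resize_long_side(image: np.ndarray, long_side: int = 608) -> np.ndarray:
    """Resize so ``max(H', W') == long_side``, aspect ratio kept to the
    nearest pixel, bilinear interpolation."""
    if long_side < 1:
        raise PreprocessError(f"long_side must be >= 1, got {long_side}")
    h, w = image.shape
    if h == 0 or w == 0:
        raise PreprocessError("empty image")
    if h >= w:
        out = (long_side, max(1, round(w * long_side / h)))
    else:
        out = (max(1, round(h * long_side / w)), long_side)
    return _bilinear_resize(image, out)


def letterbox(
    image: np.ndarray, size: int, pad_value: float = 0.0
) -> tuple[np.ndarray, dict[str, int]]:
    """Pad to a ``size x size`` canvas, content centred.

    Returns the padded image and a pad record ``{top, bottom, left,
    right}``; an odd gap puts the extra pixel on the bottom/right.
    """
    h, w = image.shape
    if size < max(h, w):
        raise PreprocessError(f"letterbox size {size} smaller than content {h}x{w}")
    gap_v, gap_h = size - h, size - w
    pads = {
        "top": gap_v // 2,
        "bottom": gap_v - gap_v // 2,
        "left": gap_h // 2,
        "right": gap_h - gap_h // 2,
    }
    out = np.full((size, size), float(pad_value))
    out[pads["top"] : pads["top"] + h, pads["left"] : pads["left"] + w] = image
    return out, pads


def crop_roi_resize(
    image: np.ndarray, box: tuple[int, int, int, int], roi_size: int = 480
) -> np.ndarray:
    """Crop a half-open 0-based box ``(r0, c0, r1, c1)`` and resize it to
    ``roi_size x roi_size``."""
    h, w = image.shape
    r0, c0, r1, c1 = box
    if r1 <= r0 or c1 <= c0:
        raise PreprocessError(f"degenerate box {box}")
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise PreprocessError(f"box {box} outside image bounds {h}x{w}")
    return _bilinear_resize(image[r0:r1, c0:c1], (roi_size, roi_size))


def normalize(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Mean-subtract and scale intensities (channel-1 constants)."""
    config = config or PreprocessConfig()
    return (image - config.mean) / config.std


def augment(
    image: np.ndarray,
    config: AugmentConfig,
    draw_seed: int,
    partner: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one seeded augmentation draw.

    Order: horizontal flip, rotation, multiplicative intensity shift,
    mixup (if a ``partner`` image is supplied).  Output is clipped to
    ``[0, 1]``; a degenerate config (all limits and probabilities zero)
    returns the input unchanged.
    """
    rng = np.random.default_rng([config.seed, int(draw_seed)])
    out = image
    if config.hflip_prob > 0 and rng.random() < config.hflip_prob:
        out = out[:, ::-1]
    if config.rotation_limit > 0:
        angle = rng.uniform(-config.rotation_limit, config.rotation_limit)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if config.intensity_shift > 0:
        out = out * (1.0 + rng.uniform(-config.intensity_shift, config.intensity_shift))
    if partner is not None and config.mixup_prob > 0 and rng.random() < config.mixup_prob:
        lam = rng.beta(config.mixup_alpha, config.mixup_alpha)
        out = lam * out + (1.0 - lam) * partner
    return np.clip(out, 0.0, 1.0)


def mosaic(images: list[np.ndarray], size: int | None = None) -> np.ndarray:
    """2 x 2 paste of four images (optional; detection-style augmentation)."""
    if len(images) != 4:
        raise PreprocessError("mosaic needs exactly 4 images")
    size = size or images[0].shape[0] * 2
    half = size // 2
    tiles = [_bilinear_resize(im, (half, half)) for im in images]
    out = np.zeros((half * 2, half * 2))
    out[:half, :half] = tiles[0]
    out[:half, half:] = tiles[1]
    out[half:, :half] = tiles[2]
    out[half:, half:] = tiles[3]
    return out
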