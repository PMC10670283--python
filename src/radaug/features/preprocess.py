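"""Image preprocessing: resampling to isotropic spacing and z-score normalization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from radaug.types import VolumeCase


@dataclass(frozen=True)
class PreprocessConfig:
    """Resample to ``target_spacing_mm``, z-score each whole image, rescale.

    Intensity discretization (fixed ``bin_width``, default 32 on the
    rescaled z-scores) is deferred to texture-matrix construction.  The
    rescale factor of 100 keeps a bin width of 32 meaningful on
    unit-variance values.
    """

    target_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    zscore: bool = True
    rescale: float = 100.0
    bin_width: float = 32.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")


def resample(volume: np.ndarray, spacing, target_spacing, order: int) -> np.ndarray:
    factors = tuple(s / t for s, t in zip(spacing, target_spacing))
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return volume.copy()
    return ndimage.zoom(volume.astype(float), factors, order=order, mode="nearest")


def zscore(image: np.ndarray, rescale: float) -> np.ndarray:
    sd = image.std()
    if sd == 0:
        raise ValueError("degenerate constant image: zero standard deviation")
    return (image - image.mean()) / sd * rescale


def preprocess(case: VolumeCase, config: PreprocessConfig) -> VolumeCase:
    """Resample images (linear) and mask (nearest-neighbor), then z-score."""
    if any(s <= 0 for s in case.spacing_mm):
        raise ValueError("input spacing must be positive")
    images = {}
    for name, im in case.images.items():
        res = resample(im, case.spacing_mm, config.target_spacing_mm, order=1)
        images[name] = zscore(res, config.rescale) if config.zscore else res
    mask = resample(case.mask.astype(np.uint8), case.spacing_mm, config.target_spacing_mm, order=0)
    mask = mask.astype(np.uint8)
    if not mask.any():
        raise ValueError("mask vanished under resampling")
    out = case.copy()
    out.images = images
    out.mask = mask
    out.spacing_mm = tuple(config.target_spacing_mm)
    return out
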