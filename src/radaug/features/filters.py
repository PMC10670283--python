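"""The 17-image filter bank applied to each preprocessed sequence.

8 filter families: original (1 image), single-level stationary 3D wavelet
(8 sub-band images), Laplacian of Gaussian at sigma 1, 3 and 5 mm (3),
square, square root, logarithm, exponential and gradient magnitude (1 each).
The pointwise filters use sign-preserving, range-normalizing conventions so
their outputs stay on a scale comparable to the input.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pywt
from scipy import ndimage

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def filter_names(log_sigmas_mm: Sequence[float] = (1.0, 3.0, 5.0)) -> list:
    names = ["original"]
    names += [f"wavelet-{b}" for b in WAVELET_BANDS]
    names += [f"log-sigma-{s:g}mm" for s in log_sigmas_mm]
    names += ["square", "squareroot", "logarithm", "exponential", "gradient"]
    return names


def _wavelet_bank(image: np.ndarray, wavelet: str) -> Dict[str, np.ndarray]:
    # swtn needs even dims; symmetric-pad odd axes and crop the result back
    pads = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pads, mode="symmetric") if any(p[1] for p in pads) else image
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    crop = tuple(slice(0, s) for s in image.shape)
    out = {}
    for band in WAVELET_BANDS:
        key = band.replace("L", "a").replace("H", "d")
        out[f"wavelet-{band}"] = coeffs[key][crop]
    return out


def _pointwise(image: np.ndarray) -> Dict[str, np.ndarray]:
    amax = np.max(np.abs(image))
    out = {}
    if amax == 0:
        out["square"] = np.zeros_like(image)
        out["squareroot"] = np.zeros_like(image)
        out["logarithm"] = np.zeros_like(image)
        out["exponential"] = np.ones_like(image)
        return out
    out["square"] = (image / np.sqrt(amax)) ** 2
    out["squareroot"] = np.sign(image) * np.sqrt(amax * np.abs(image))
    out["logarithm"] = np.sign(image) * (amax / np.log(amax + 1.0)) * np.log(np.abs(image) + 1.0)
    out["exponential"] = np.exp(image * (np.log(amax) / amax))
    return out


def build_filter_bank(
    image: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    wavelet: str = "coif1",
    log_sigmas_mm: Sequence[float] = (1.0, 3.0, 5.0),
    only: Sequence[str] = None,
) -> Dict[str, np.ndarray]:
    """Return the named filter images for one preprocessed sequence.

    By default all 17 images are computed; ``only`` restricts computation
    to the named subset (reduced extraction profiles).
    """
    if min(image.shape) < 4:
        raise ValueError("image smaller than wavelet/LoG filter support")
    wanted = set(filter_names(log_sigmas_mm) if only is None else only)
    spacing = np.asarray(spacing_mm, dtype=float)
    bank: Dict[str, np.ndarray] = {}
    if "original" in wanted:
        bank["original"] = image.copy()
    if any(n.startswith("wavelet-") for n in wanted):
        bank.update(_wavelet_bank(image, wavelet))
    for s in log_sigmas_mm:
        name = f"log-sigma-{s:g}mm"
        if name in wanted:
            bank[name] = ndimage.gaussian_laplace(image, s / spacing)
    if wanted & {"square", "squareroot", "logarithm", "exponential"}:
        bank.update(_pointwise(image))
    if "gradient" in wanted:
        grads = np.gradient(image, *spacing)
        bank["gradient"] = np.sqrt(sum(g**2 for g in grads))
    if only is None:
        assert len(bank) == 17
    return bank
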