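"""18 first-order intensity statistics of the masked voxels."""

from __future__ import annotations

from typing import Dict

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(values: np.ndarray, voxel_volume_mm3: float, bin_width: float) -> Dict[str, float]:
    """Compute the 18 statistics on a 1D array of masked intensities.

    Entropy and Uniformity use the fixed-bin-width discretization shared
    with the texture matrices.  Skewness is the population third standard
    moment; Kurtosis is the non-excess fourth (3.0 for a normal sample in
    the large-n limit).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty mask")
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    edges_n = int(np.floor((x.max() - x.min()) / bin_width)) + 1
    counts = np.bincount(np.minimum(((x - x.min()) // bin_width).astype(int), edges_n - 1), minlength=edges_n)
    p = counts[counts > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    skew = (np.mean((x - mean) ** 3) / sd**3) if sd > 0 else 0.0
    kurt = (np.mean((x - mean) ** 4) / m2**2) if m2 > 0 else 0.0

    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
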