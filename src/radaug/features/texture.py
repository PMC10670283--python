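"""Texture feature formulas for the five gray-level matrix families.

24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM = 75 features.
GLCM and GLRLM values are averaged over the 13 directions; GLSZM, NGTDM
and GLDM are direction-free.  Degenerate inputs (single gray level,
single voxel) take the standard limiting values so no feature is ever
non-finite.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

EPS = np.finfo(float).eps

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

TEXTURE_CLASS_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


def _glcm_single(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ks])
    kd = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in kd])

    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))

    autoc = float(np.sum(p * ii * jj))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    corr = float((autoc - mu_x * mu_y) / (sig_x * sig_y)) if sig_x > 0 and sig_y > 0 else 1.0
    da = float(np.sum(p_diff * kd))
    de = float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])))
    dv = float(np.sum(p_diff * (kd - da) ** 2))
    imc1 = float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    inv_var = float(np.sum(p[ii != jj] / (ii - jj)[ii != jj].astype(float) ** 2)) if ng > 1 else 0.0

    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / np.where(px[:, None] > 0, px[:, None], 1.0)) @ (
                p / np.where(py[None, :] > 0, py[None, :], 1.0)
            ).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": de,
        "DifferenceVariance": dv,
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(p_sum * ks)),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def glcm_features(p_per_direction: Sequence[np.ndarray]) -> Dict[str, float]:
    per = [_glcm_single(p) for p in p_per_direction]
    return {k: float(np.mean([d[k] for d in per])) for k in GLCM_NAMES}


def _rlm_like(mat: np.ndarray, n_voxels: int, run_axis_name: str) -> Dict[str, float]:
    """Shared formulas for run-length-style matrices (GLRLM and GLDM)."""
    nr = mat.sum()
    if nr == 0:
        raise ValueError("empty matrix")
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, nl + 1)[None, :].astype(float)
    p = mat / nr
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    pn = p[p > 0]
    out = {
        f"Short{run_axis_name}Emphasis": float(np.sum(mat / j**2) / nr),
        f"Long{run_axis_name}Emphasis": float(np.sum(mat * j**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(ri**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(ri**2) / nr**2),
        f"{run_axis_name}LengthNonUniformity": float(np.sum(rj**2) / nr),
        f"{run_axis_name}LengthNonUniformityNormalized": float(np.sum(rj**2) / nr**2),
        f"{run_axis_name}Percentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        f"{run_axis_name}Variance": float(np.sum(p * (j - mu_j) ** 2)),
        f"{run_axis_name}Entropy": float(-np.sum(pn * np.log2(pn))),
        f"LowGrayLevel{run_axis_name}Emphasis": float(np.sum(mat / i**2) / nr),
        f"HighGrayLevel{run_axis_name}Emphasis": float(np.sum(mat * i**2) / nr),
        f"Short{run_axis_name}LowGrayLevelEmphasis": float(np.sum(mat / (i**2 * j**2)) / nr),
        f"Short{run_axis_name}HighGrayLevelEmphasis": float(np.sum(mat * i**2 / j**2) / nr),
        f"Long{run_axis_name}LowGrayLevelEmphasis": float(np.sum(mat * j**2 / i**2) / nr),
        f"Long{run_axis_name}HighGrayLevelEmphasis": float(np.sum(mat * i**2 * j**2) / nr),
    }
    return out


def glrlm_features(mats: Sequence[np.ndarray], n_voxels: int) -> Dict[str, float]:
    per = []
    for mat in mats:
        raw = _rlm_like(mat, n_voxels, "Run")
        per.append({
            "ShortRunEmphasis": raw["ShortRunEmphasis"],
            "LongRunEmphasis": raw["LongRunEmphasis"],
            "GrayLevelNonUniformity": raw["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": raw["GrayLevelNonUniformityNormalized"],
            "RunLengthNonUniformity": raw["RunLengthNonUniformity"],
            "RunLengthNonUniformityNormalized": raw["RunLengthNonUniformityNormalized"],
            "RunPercentage": raw["RunPercentage"],
            "GrayLevelVariance": raw["GrayLevelVariance"],
            "RunVariance": raw["RunVariance"],
            "RunEntropy": raw["RunEntropy"],
            "LowGrayLevelRunEmphasis": raw["LowGrayLevelRunEmphasis"],
            "HighGrayLevelRunEmphasis": raw["HighGrayLevelRunEmphasis"],
            "ShortRunLowGrayLevelEmphasis": raw["ShortRunLowGrayLevelEmphasis"],
            "ShortRunHighGrayLevelEmphasis": raw["ShortRunHighGrayLevelEmphasis"],
            "LongRunLowGrayLevelEmphasis": raw["LongRunLowGrayLevelEmphasis"],
            "LongRunHighGrayLevelEmphasis": raw["LongRunHighGrayLevelEmphasis"],
        })
    return {k: float(np.mean([d[k] for d in per])) for k in GLRLM_NAMES}


def glszm_features(mat: np.ndarray, n_voxels: int) -> Dict[str, float]:
    nz = mat.sum()
    ng, ns = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, ns + 1)[None, :].astype(float)
    p = mat / nz
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    zi = mat.sum(axis=1)
    zj = mat.sum(axis=0)
    pn = p[p > 0]
    return {
        "SmallAreaEmphasis": float(np.sum(mat / j**2) / nz),
        "LargeAreaEmphasis": float(np.sum(mat * j**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(zi**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(zi**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(zj**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(zj**2) / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "ZoneEntropy": float(-np.sum(pn * np.log2(pn))),
        "LowGrayLevelZoneEmphasis": float(np.sum(mat / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(mat * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * j**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(mat * i**2 / j**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(mat * j**2 / i**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(mat * i**2 * j**2) / nz),
    }


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> Dict[str, float]:
    n_total = n_i.sum()
    if n_total == 0:
        # single isolated voxel: no neighborhood anywhere
        return {k: 0.0 if k != "Coarseness" else 1e6 for k in NGTDM_NAMES}
    p_i = n_i / n_total
    ng = len(n_i)
    i = np.arange(1, ng + 1).astype(float)
    present = p_i > 0
    ngp = int(present.sum())

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi_p, ii_p = p_i[present], i[present]
        pp = np.outer(pi_p, pi_p)
        dd = (ii_p[:, None] - ii_p[None, :]) ** 2
        contrast = float(pp.ravel() @ dd.ravel() / (ngp * (ngp - 1)) * (s_i.sum() / n_total))
        busy_den = float(np.sum(np.abs(ii_p[:, None] * pi_p[:, None] - ii_p[None, :] * pi_p[None, :])))
        busyness = float(np.sum(p_i * s_i) / busy_den) if busy_den > 0 else 0.0
        absdiff = np.abs(ii_p[:, None] - ii_p[None, :])
        num = pi_p[:, None] * s_i[present][:, None] + pi_p[None, :] * s_i[present][None, :]
        den = pi_p[:, None] + pi_p[None, :]
        complexity = float(np.sum(absdiff * num / den) / n_total)
        s_sum = s_i.sum()
        strength = float(np.sum((pi_p[:, None] + pi_p[None, :]) * dd) / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def gldm_features(mat: np.ndarray, n_voxels: int) -> Dict[str, float]:
    raw = _rlm_like(mat, n_voxels, "Dependence")
    return {
        "SmallDependenceEmphasis": raw["ShortDependenceEmphasis"],
        "LargeDependenceEmphasis": raw["LongDependenceEmphasis"],
        "GrayLevelNonUniformity": raw["GrayLevelNonUniformity"],
        "DependenceNonUniformity": raw["DependenceLengthNonUniformity"],
        "DependenceNonUniformityNormalized": raw["DependenceLengthNonUniformityNormalized"],
        "GrayLevelVariance": raw["GrayLevelVariance"],
        "DependenceVariance": raw["DependenceVariance"],
        "DependenceEntropy": raw["DependenceEntropy"],
        "LowGrayLevelEmphasis": raw["LowGrayLevelDependenceEmphasis"],
        "HighGrayLevelEmphasis": raw["HighGrayLevelDependenceEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": raw["ShortDependenceLowGrayLevelEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": raw["ShortDependenceHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": raw["LongDependenceLowGrayLevelEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": raw["LongDependenceHighGrayLevelEmphasis"],
    }
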