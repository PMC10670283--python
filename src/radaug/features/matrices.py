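"""Gray-level texture matrices on discretized 3D volumes.

All five families (GLCM, GLRLM, GLSZM, NGTDM, GLDM) operate on the same
discretization: masked intensities binned with a fixed bin width, bins
numbered from 1; voxels outside the mask carry 0.  Co-occurrence and
run-length use the 13 unique direction pairs of the 26-neighborhood at
distance 1; zones, gray-tone differences and dependences use full
26-connectivity.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy import ndimage

# 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

NEIGHBORS_26: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> Tuple[np.ndarray, int]:
    """Fixed-bin-width discretization of masked voxels; 0 marks background.

    Returns the discretized volume (int, bins from 1) and the number of
    gray levels Ng.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    lo = vals.min()
    bins = np.floor((image - lo) / bin_width).astype(int) + 1
    disc = np.where(mask, bins, 0)
    return disc, int(disc.max())


def _shifted(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """out[p] = arr[p + d] where valid, else fill."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for di, s in zip(d, arr.shape):
        if di >= 0:
            dst.append(slice(0, s - di))
            src.append(slice(di, s))
        else:
            dst.append(slice(-di, s))
            src.append(slice(0, s + di))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glcm_matrices(disc: np.ndarray, ng: int) -> List[np.ndarray]:
    """Per-direction symmetric normalized co-occurrence matrices."""
    valid = disc > 0
    out = []
    for d in DIRECTIONS_13:
        b = _shifted(disc, d)
        ok = valid & (b > 0)
        if not ok.any():
            continue
        a_v = disc[ok] - 1
        b_v = b[ok] - 1
        counts = np.bincount(a_v * ng + b_v, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T
        out.append(counts / counts.sum())
    if not out:  # single-voxel mask: no pairs in any direction
        out = [np.ones((1, 1))]
    return out


def glrlm_matrices(disc: np.ndarray, ng: int) -> List[np.ndarray]:
    """Per-direction run-length count matrices (Ng x max_run_length)."""
    valid = disc > 0
    max_len = max(disc.shape)
    out = []
    for d in DIRECTIONS_13:
        prev = _shifted(disc, tuple(-x for x in d))
        cont = valid & (prev == disc) & (prev > 0)  # continues the run from p-d
        follow = _shifted(cont.astype(np.int64), d)  # 1 if p+d continues from p
        t = np.zeros_like(disc, dtype=np.int64)
        for _ in range(max_len):
            nt = follow * (1 + _shifted(t, d))
            if np.array_equal(nt, t):
                break
            t = nt
        starts = valid & ~cont
        lengths = 1 + t[starts]
        levels = disc[starts]
        r = np.bincount((levels - 1) * max_len + (lengths - 1), minlength=ng * max_len)
        out.append(r.reshape(ng, max_len).astype(float))
    return out


def glszm_matrix(disc: np.ndarray, ng: int) -> np.ndarray:
    """Zone-size count matrix by 26-connectivity (Ng x max_zone_size)."""
    structure = np.ones((3, 3, 3), dtype=int)
    entries = []
    max_size = 1
    for g in range(1, ng + 1):
        region = disc == g
        if not region.any():
            continue
        labeled, n = ndimage.label(region, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            entries.append((g, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((ng, max_size), dtype=float)
    for g, s in entries:
        mat[g - 1, s - 1] += 1
    return mat


def ngtdm_components(disc: np.ndarray, ng: int) -> Tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) for i = 1..Ng over the 26-neighborhood.

    n_i counts masked voxels of level i that have at least one masked
    neighbor; s_i sums |i - neighborhood average| over those voxels.
    """
    valid = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=float)
    nb_cnt = np.zeros(disc.shape, dtype=float)
    for d in NEIGHBORS_26:
        nb_sum += _shifted(np.where(valid, disc, 0).astype(float), d)
        nb_cnt += _shifted(valid.astype(float), d)
    use = valid & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(use, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    diff = np.abs(disc - abar)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for g in range(1, ng + 1):
        sel = use & (disc == g)
        n_i[g - 1] = sel.sum()
        s_i[g - 1] = diff[sel].sum()
    return n_i, s_i


def gldm_matrix(disc: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix: (Ng x max_dependence), 26-neighborhood.

    The dependence of a voxel is 1 + the number of masked neighbors whose
    level differs by at most ``alpha``.
    """
    valid = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for d in NEIGHBORS_26:
        nb = _shifted(disc, d)
        dep += (valid & (nb > 0) & (np.abs(nb - disc) <= alpha)).astype(np.int64)
    j = dep[valid] + 1
    levels = disc[valid]
    max_dep = int(j.max())
    mat = np.bincount((levels - 1) * max_dep + (j - 1), minlength=ng * max_dep)
    return mat.reshape(ng, max_dep).astype(float)
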