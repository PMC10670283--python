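"""Texture matrices against brute-force enumeration oracles."""

import numpy as np
import pytest

from radaug.features import matrices as mx
from radaug.features import texture as tx


def brute_force_glcm(disc, ng, d):
    """Exhaustive pair enumeration oracle for one direction."""
    counts = np.zeros((ng, ng))
    shape = disc.shape
    for idx in np.ndindex(shape):
        nb = tuple(i + o for i, o in zip(idx, d))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            a, b = disc[idx], disc[nb]
            if a > 0 and b > 0:
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def test_direction_set_is_13_unique():
    assert len(mx.DIRECTIONS_13) == 13
    as_set = set(mx.DIRECTIONS_13)
    for d in mx.DIRECTIONS_13:
        assert tuple(-x for x in d) not in as_set
    assert len(mx.NEIGHBORS_26) == 26


def test_glcm_matches_pair_enumeration_oracle(rng):
    img = rng.uniform(0, 100, size=(3, 3, 3))
    mask = rng.uniform(size=(3, 3, 3)) > 0.3
    mask.flat[0] = True
    disc, ng = mx.discretize(img, mask, bin_width=25.0)
    mats = mx.glcm_matrices(disc, ng)
    oracle = []
    for d in mx.DIRECTIONS_13:
        c = brute_force_glcm(disc, ng, d)
        if c.sum() > 0:
            oracle.append(c / c.sum())
    assert len(mats) == len(oracle)
    for m, o in zip(mats, oracle):
        assert np.allclose(m, o)


def test_glcm_normalized_symmetric_nonnegative(case32):
    disc, ng = mx.discretize(case32.images["T2W"], case32.mask.astype(bool), bin_width=30.0)
    for p in mx.glcm_matrices(disc, ng):
        assert np.isclose(p.sum(), 1.0)
        assert np.allclose(p, p.T)
        assert (p >= 0).all()


def test_uniform_mask_glcm_entropy_zero():
    img = np.full((4, 4, 4), 5.0)
    mask = np.ones((4, 4, 4), dtype=bool)
    disc, ng = mx.discretize(img, mask, bin_width=1.0)
    feats = tx.glcm_features(mx.glcm_matrices(disc, ng))
    assert feats["JointEntropy"] == 0.0
    assert feats["MaximumProbability"] == 1.0


def brute_force_runs(disc, d):
    """Enumerate runs along direction d by walking every line."""
    shape = disc.shape
    runs = []
    for start in np.ndindex(shape):
        prev = tuple(s - o for s, o in zip(start, d))
        starts_line = not all(0 <= p < s for p, s in zip(prev, shape))
        if not starts_line:
            continue
        pos, line = start, []
        while all(0 <= p < s for p, s in zip(pos, shape)):
            line.append(disc[pos])
            pos = tuple(p + o for p, o in zip(pos, d))
        # split line into maximal runs of equal nonzero values
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            runs.append((line[i], j - i + 1))
            i = j + 1
    return runs


def test_glrlm_matches_line_walking_oracle(rng):
    img = rng.uniform(0, 100, size=(4, 4, 4))
    mask = rng.uniform(size=(4, 4, 4)) > 0.25
    mask.flat[0] = True
    disc, ng = mx.discretize(img, mask, bin_width=30.0)
    mats = mx.glrlm_matrices(disc, ng)
    max_len = max(disc.shape)
    for mat, d in zip(mats, mx.DIRECTIONS_13):
        oracle = np.zeros((ng, max_len))
        for level, length in brute_force_runs(disc, d):
            oracle[level - 1, length - 1] += 1
        assert np.array_equal(mat, oracle), f"direction {d}"


def test_glrlm_voxel_count_identity(case32):
    """Sum over runs of level x length recovers the masked voxel count."""
    disc, ng = mx.discretize(case32.images["T2W"], case32.mask.astype(bool), bin_width=40.0)
    n_vox = int((disc > 0).sum())
    lengths = np.arange(1, max(disc.shape) + 1)
    for mat in mx.glrlm_matrices(disc, ng):
        assert int((mat * lengths[None, :]).sum()) == n_vox


def test_glszm_single_voxel_mask():
    img = np.zeros((5, 5, 5))
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    disc, ng = mx.discretize(img, mask, bin_width=1.0)
    mat = mx.glszm_matrix(disc, ng)
    assert mat.shape == (1, 1)
    assert mat[0, 0] == 1  # exactly one zone of size 1


def test_glszm_zone_decomposition():
    """Two separated same-level blobs are two zones; sizes sum to voxels."""
    disc = np.zeros((6, 6, 6), dtype=int)
    disc[0:2, 0:2, 0:2] = 1  # 8-voxel zone
    disc[4:6, 4:6, 4:6] = 1  # second 8-voxel zone (not 26-connected)
    disc[0, 5, 0] = 2  # single voxel of another level
    mat = mx.glszm_matrix(disc, 2)
    assert mat[0, 7] == 2  # two zones of size 8
    assert mat[1, 0] == 1
    sizes = np.arange(1, mat.shape[1] + 1)
    assert int((mat * sizes[None, :]).sum()) == int((disc > 0).sum())


def test_gldm_dependence_counts():
    """Uniform 3x3x3 block: center depends on all 26 neighbors."""
    disc = np.zeros((5, 5, 5), dtype=int)
    disc[1:4, 1:4, 1:4] = 1
    mat = mx.gldm_matrix(disc, 1, alpha=0)
    assert int(mat.sum()) == 27
    assert mat[0, 26] == 1  # the center voxel: dependence 26 + 1
    sizes_total = mat.sum()
    assert sizes_total == (disc > 0).sum()


def test_ngtdm_uniform_block_zero_differences():
    disc = np.zeros((5, 5, 5), dtype=int)
    disc[1:4, 1:4, 1:4] = 1
    n_i, s_i = mx.ngtdm_components(disc, 1)
    assert n_i[0] == 27
    assert np.allclose(s_i, 0.0)
    feats = tx.ngtdm_features(n_i, s_i)
    assert feats["Coarseness"] == 1e6  # zero-denominator convention


def test_texture_class_counts_sum_to_75():
    counts = {k: len(v) for k, v in tx.TEXTURE_CLASS_NAMES.items()}
    assert counts == {"glcm": 24, "glrlm": 16, "glszm": 16, "ngtdm": 5, "gldm": 14}
    assert sum(counts.values()) == 75


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty mask"):
        mx.discretize(np.ones((3, 3, 3)), np.zeros((3, 3, 3), dtype=bool), 1.0)
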