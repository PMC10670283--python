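"""Preprocessing, filter bank, first-order and shape features against
independent arithmetic/geometry oracles."""

import numpy as np
import pytest

from radaug.features.filters import build_filter_bank, filter_names
from radaug.features.firstorder import FIRSTORDER_NAMES, firstorder_features
from radaug.features.preprocess import PreprocessConfig, preprocess, zscore
from radaug.features.shape import SHAPE_NAMES, shape_features
from radaug.types import VolumeCase


# ---------- preprocessing ----------

def test_zscore_normalizes_to_rescale_factor(case32):
    out = preprocess(case32, PreprocessConfig())
    for img in out.images.values():
        assert abs(img.mean()) < 1e-8
        assert abs(img.std() - 100.0) < 1e-6


def test_resample_identity_at_target_spacing(case32):
    out = preprocess(case32, PreprocessConfig(zscore=False))
    assert out.images["T2W"].shape == case32.images["T2W"].shape
    assert np.allclose(out.images["T2W"], case32.images["T2W"])


def test_resampling_changes_grid():
    vol = np.random.default_rng(0).uniform(1, 2, size=(10, 10, 10))
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask[3:7, 3:7, 3:7] = 1
    case = VolumeCase("c", {"T2W": vol, "T1C": vol + 1}, mask, (2.0, 2.0, 2.0), 0)
    out = preprocess(case, PreprocessConfig())
    assert out.images["T2W"].shape == (20, 20, 20)
    assert out.mask.shape == (20, 20, 20)
    assert set(np.unique(out.mask)) <= {0, 1}


def test_toy_zscore_hand_computed():
    grid = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
    out = zscore(grid, rescale=1.0)
    mean, sd = 4.5, np.sqrt(np.mean((grid - 4.5) ** 2))
    assert np.allclose(out, (grid - mean) / sd)


def test_constant_image_rejected(case32):
    bad = case32.copy()
    bad.images["T2W"] = np.ones_like(bad.images["T2W"])
    with pytest.raises(ValueError, match="zero standard deviation"):
        preprocess(bad, PreprocessConfig())


# ---------- filter bank ----------

def test_filter_bank_has_17_images(case32):
    bank = build_filter_bank(case32.images["T2W"])
    assert len(bank) == 17
    assert set(bank) == set(filter_names())


def test_log_of_constant_image_is_zero():
    bank = build_filter_bank(np.full((16, 16, 16), 3.0))
    for s in (1, 3, 5):
        # boundary handling leaves tiny residuals relative to the image scale
        assert np.abs(bank[f"log-sigma-{s}mm"]).max() < 1e-2


def test_gradient_matches_finite_difference_oracle():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(8, 8, 8))
    bank = build_filter_bank(img)
    # independent central/one-sided difference oracle at an interior voxel
    i, j, k = 4, 3, 5
    gx = (img[i + 1, j, k] - img[i - 1, j, k]) / 2
    gy = (img[i, j + 1, k] - img[i, j - 1, k]) / 2
    gz = (img[i, j, k + 1] - img[i, j, k - 1]) / 2
    assert np.isclose(bank["gradient"][i, j, k], np.sqrt(gx**2 + gy**2 + gz**2))


def test_small_image_rejected():
    with pytest.raises(ValueError, match="support"):
        build_filter_bank(np.ones((3, 3, 3)))


# ---------- first-order ----------

def test_firstorder_matches_direct_arithmetic(rng):
    vals = rng.normal(50, 10, size=500)
    feats = firstorder_features(vals, voxel_volume_mm3=2.0, bin_width=5.0)
    assert set(feats) == set(FIRSTORDER_NAMES) and len(feats) == 18
    assert np.isclose(feats["Mean"], vals.mean())
    assert np.isclose(feats["Variance"], vals.var())
    assert np.isclose(feats["Minimum"], vals.min())
    assert np.isclose(feats["Maximum"], vals.max())
    assert np.isclose(feats["Median"], np.median(vals))
    assert np.isclose(feats["Energy"], (vals**2).sum())
    assert np.isclose(feats["TotalEnergy"], 2.0 * (vals**2).sum())
    assert np.isclose(feats["RootMeanSquared"], np.sqrt((vals**2).mean()))
    assert np.isclose(feats["Range"], np.ptp(vals))
    assert np.isclose(feats["MeanAbsoluteDeviation"], np.abs(vals - vals.mean()).mean())


def test_firstorder_uniformity_entropy_limits():
    const = firstorder_features(np.full(100, 7.0), 1.0, bin_width=1.0)
    assert const["Entropy"] == 0.0
    assert const["Uniformity"] == 1.0


# ---------- shape ----------

def test_shape_feature_count_and_names(case32):
    feats = shape_features(case32.mask, case32.spacing_mm)
    assert set(feats) == set(SHAPE_NAMES) and len(feats) == 14


def test_sphere_sphericity_close_to_one():
    grid = np.indices((40, 40, 40)).astype(float)
    r2 = sum((g - 19.5) ** 2 for g in grid)
    sphere = (r2 <= 15.0**2).astype(np.uint8)
    feats = shape_features(sphere)
    # the analytic bound is <= 1; the staircase surface of a binary mask
    # inflates the measured area, so discretized spheres land below 1
    assert feats["Sphericity"] <= 1.0
    assert feats["Sphericity"] > 0.85
    assert np.isclose(feats["Elongation"], 1.0, atol=0.02)
    assert np.isclose(feats["Flatness"], 1.0, atol=0.02)


def test_box_mask_analytic_values():
    mask = np.zeros((20, 20, 20), dtype=np.uint8)
    mask[5:15, 5:11, 5:9] = 1  # 10 x 6 x 4 box
    feats = shape_features(mask, (1.0, 1.0, 1.0))
    assert feats["VoxelVolume"] == 10 * 6 * 4
    # voxel-center diagonal of the box
    expected_diam = np.sqrt(9**2 + 5**2 + 3**2)
    assert np.isclose(feats["Maximum3DDiameter"], expected_diam)
    # max in-plane diameter across the first axis: 6 x 4 cross-section
    assert np.isclose(feats["Maximum2DDiameterSlice"], np.sqrt(5**2 + 3**2))
    assert feats["MajorAxisLength"] >= feats["MinorAxisLength"] >= feats["LeastAxisLength"]


def test_single_voxel_mask_is_finite():
    mask = np.zeros((8, 8, 8), dtype=np.uint8)
    mask[4, 4, 4] = 1
    feats = shape_features(mask)
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["VoxelVolume"] == 1.0
    assert feats["Maximum3DDiameter"] == 0.0
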