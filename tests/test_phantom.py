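import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from radaug.phantom import generate_cohort, read_cohort, render_case, write_cohort
from radaug.features.shape import shape_features
from radaug.types import PhantomConfig


def test_cohort_counts_and_labels(small_cohort, small_config):
    assert len(small_cohort) == small_config.n_majority + small_config.n_minority
    labels = [c.label for c in small_cohort]
    assert labels.count(0) == small_config.n_majority
    assert labels.count(1) == small_config.n_minority


def test_cohort_deterministic_under_master_seed(small_config):
    a = generate_cohort(small_config)
    b = generate_cohort(small_config)
    for ca, cb in zip(a, b):
        assert np.array_equal(ca.mask, cb.mask)
        for s in ca.sequence_names:
            assert np.array_equal(ca.images[s], cb.images[s])


def test_masks_are_single_connected_components(small_cohort):
    for c in small_cohort:
        assert c.mask.sum() > 0
        _, n = ndimage.label(c.mask)
        assert n == 1


def test_default_cohort_ratio():
    """The default configuration emulates a 129:31 imbalanced cohort."""
    cfg = PhantomConfig()
    assert cfg.n_majority + cfg.n_minority == 160
    assert (cfg.n_majority, cfg.n_minority) == (129, 31)


def test_oversized_tumor_config_rejected():
    cfg = PhantomConfig(volume_shape=(16, 16, 16), tumor_radius_range_mm=(6.0, 10.0))
    with pytest.raises(ValueError, match="too small"):
        cfg.validate()


def test_invalid_class_signal_rejected():
    cfg = PhantomConfig(heterogeneity_majority=0.2, heterogeneity_minority=0.1)
    with pytest.raises(ValueError):
        cfg.validate()


def test_label_flip_keeps_geometry_changes_texture(small_config):
    """The label only selects amplitudes; geometry streams are separate."""
    cfg = dataclasses.replace(small_config, margin_irregularity_minority=0.0)
    low = render_case(0, np.random.SeedSequence(99), cfg)
    high = render_case(1, np.random.SeedSequence(99), cfg)
    assert np.array_equal(low.mask, high.mask)
    assert not np.array_equal(low.images["T2W"], high.images["T2W"])
    # minority texture must have strictly larger within-mask variation
    m = low.mask.astype(bool)
    assert high.images["T2W"][m].std() > low.images["T2W"][m].std()


def test_irregular_margins_reduce_sphericity(small_config):
    """Minority masks with margin perturbation are less spherical."""
    cfg = dataclasses.replace(small_config, margin_irregularity_minority=0.25)
    sph = {label: [] for label in (0, 1)}
    for seed in range(6):
        ss = np.random.SeedSequence(1000 + seed)
        for label in (0, 1):
            case = render_case(label, ss, cfg)
            sph[label].append(shape_features(case.mask, case.spacing_mm)["Sphericity"])
    assert np.mean(sph[0]) > np.mean(sph[1])


def test_mask_matches_analytic_ellipsoid_band(small_config):
    """Foreground count stays within the perturbation band of the ellipsoid."""
    cfg = dataclasses.replace(small_config, margin_irregularity_minority=0.2)
    ss = np.random.SeedSequence(5)
    case = render_case(1, ss, cfg)
    # brute-force bound: perturbed radius is within (1 +/- irregularity) x radii,
    # so the voxel count lies between the shrunken and inflated ellipsoid counts
    lo, hi = cfg.tumor_radius_range_mm
    vol = case.mask.sum()
    vox = np.prod(case.spacing_mm)
    v_min = 4 / 3 * np.pi * (lo * (1 - 0.2)) ** 3 / vox
    v_max = 4 / 3 * np.pi * (hi * (1 + 0.2)) ** 3 / vox
    assert v_min * 0.7 <= vol <= v_max * 1.3  # 30% discretization slack


def test_effect_size_dial_feature_separability():
    """Raising the heterogeneity contrast drives single-feature class
    separability from chance toward 1 (the dial the experiments turn)."""
    from radaug.features.extract import extract_table
    from radaug.features.schema import ExtractionProfile
    from sklearn.metrics import roc_auc_score

    def best_feature_auc(het_minority):
        cfg = PhantomConfig(
            n_majority=12, n_minority=8, volume_shape=(16, 16, 16),
            tumor_radius_range_mm=(3.0, 4.5), heterogeneity_majority=0.10,
            heterogeneity_minority=het_minority, margin_irregularity_minority=0.0,
            heterogeneity_jitter_sigma=0.1, acquisition_bias=0.0,
            acquisition_gamma_log=0.0, master_seed=31,
        )
        tab = extract_table(generate_cohort(cfg, allow_null=True),
                            profile=ExtractionProfile(filters=("original",), classes=("firstorder",)))
        y = tab.labels.to_numpy()
        best = 0.5
        for col in tab.columns:
            v = tab.features[col].to_numpy()
            if v.std() > 0:
                a = roc_auc_score(y, v)
                best = max(best, a, 1 - a)
        return best

    weak, strong = best_feature_auc(0.105), best_feature_auc(0.60)
    assert strong > 0.95
    assert weak < strong


def test_nifti_round_trip(tmp_path, small_cohort):
    manifest = write_cohort(small_cohort[:3], str(tmp_path))
    back = read_cohort(manifest)
    assert len(back) == 3
    for orig, rt in zip(small_cohort[:3], back):
        assert rt.case_id == orig.case_id
        assert rt.label == orig.label
        assert np.array_equal(rt.mask, orig.mask)
        assert np.allclose(rt.images["T2W"], orig.images["T2W"], atol=1e-4)
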