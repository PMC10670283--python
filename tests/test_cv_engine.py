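"""Cross-validation orchestration: contracts, leakage safety, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from radaug.cv import make_fold_plan
from radaug.experiment import (
    ExperimentConfig,
    _augmented_table,
    _run_fold,
    run_experiment,
    run_naive_split,
    summarize,
)
from radaug.features.extract import FeatureTable
from radaug.features.schema import ExtractionProfile
from radaug.grid import PipelineSetting
from radaug.phantom import generate_cohort
from radaug.types import PhantomConfig


def _fast_config(**kw):
    defaults = dict(
        setting=PipelineSetting("CHSQ", "LASSO", "LR"),
        modes=("None", "FA"),
        k=3,
        repetitions=2,
        profile=ExtractionProfile.light(),
        seed=5,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="module")
def cohort20():
    cfg = PhantomConfig(
        n_majority=14, n_minority=6, volume_shape=(16, 16, 16),
        tumor_radius_range_mm=(3.0, 4.5), heterogeneity_majority=0.10,
        heterogeneity_minority=0.14, margin_irregularity_minority=0.08,
        master_seed=17,
    )
    return generate_cohort(cfg)


def test_experiment_structure_and_determinism(cohort20):
    config = _fast_config()
    res_a = run_experiment(cohort20, config)
    res_b = run_experiment(cohort20, config)
    assert set(res_a) == {"None", "FA"}
    for mode in res_a:
        assert len(res_a[mode]) == 2  # one TrialResult per repetition
        for ta, tb in zip(res_a[mode], res_b[mode]):
            assert ta.cv_auc == tb.cv_auc
            assert ta.fold_aucs == tb.fold_aucs
            assert len(ta.fold_aucs) == 3
            assert 0.0 <= ta.cv_auc <= 1.0
            assert ta.mean_auc == pytest.approx(np.mean(ta.fold_aucs))


def test_augmented_table_row_count(cohort20):
    """IA expands each training case to original + 9 copies before extraction."""
    config = _fast_config(modes=("IA",))
    sub = cohort20[:4]
    table, intensity_ids = _augmented_table(sub, config, [1, 2, 3, 4])
    assert len(table) == 9 * len(sub)
    assert len(intensity_ids) == 5 * len(sub)
    assert set(table.parent_id) == {c.case_id for c in sub}


def test_no_augmented_parent_in_test_fold(cohort20):
    """Augmented rows used for training never descend from held-out cases."""
    config = _fast_config(modes=("IAFA",), repetitions=1)
    ids = [c.case_id for c in cohort20]
    labels = [c.label for c in cohort20]
    plan = make_fold_plan(labels, 3, 1, seed=1)
    table, intensity_ids = _augmented_table(cohort20, config, list(range(len(cohort20))))
    from radaug.features.extract import extract_table

    base = extract_table(cohort20, config.preprocess, config.profile)
    test_ids = [ids[i] for i in np.flatnonzero(plan.assignment[0] == 0)]
    train_ids = [i for i in ids if i not in test_ids]
    aug_train = table.parent_id.index[table.parent_id.isin(train_ids)]
    assert not set(table.parent_id.loc[aug_train]) & set(test_ids)
    probs, y_te, _ = _run_fold(base, table, train_ids, test_ids, "IAFA", config, 3, 4, intensity_ids)
    assert len(probs) == len(test_ids)
    assert np.all((probs >= 0) & (probs <= 1))


def _synthetic_table(rng, n=36, p=20):
    ids = [f"c{i}" for i in range(n)]
    labels = pd.Series([0] * (2 * n // 3) + [1] * (n - 2 * n // 3), index=ids)
    x = rng.normal(size=(n, p))
    df = pd.DataFrame(x, index=ids, columns=[f"f{j}" for j in range(p)])
    return FeatureTable(df, labels, pd.Series(ids, index=ids))


def test_leakage_canary(rng):
    """A feature equal to the labels on TEST rows but noise on train rows
    must not help: selection and fitting see training data only."""
    n = 36
    table = _synthetic_table(rng, n=n)
    labels = table.labels.to_numpy()
    plan = make_fold_plan(labels, 3, 1, seed=3)
    config = _fast_config(modes=("None",), repetitions=1)
    ids = list(table.features.index)

    aucs = []
    for _ in range(10):
        canary_tab = FeatureTable(table.features.copy(), table.labels, table.parent_id)
        probs_all, labels_all = [], []
        for f in range(3):
            test_ids = [ids[i] for i in np.flatnonzero(plan.assignment[0] == f)]
            train_ids = [i for i in ids if i not in test_ids]
            canary = pd.Series(rng.normal(size=n), index=ids)
            canary.loc[test_ids] = table.labels.loc[test_ids].astype(float)  # leak target
            canary_tab.features["f0"] = canary
            probs, y_te, _ = _run_fold(canary_tab, None, train_ids, test_ids, "None", config, 0, 0)
            probs_all.append(probs)
            labels_all.append(y_te)
        from radaug.cv import cv_auc

        aucs.append(cv_auc(probs_all, labels_all))
    assert abs(np.mean(aucs) - 0.5) < 0.2  # chance level, not inflated by the leak


def test_run_naive_split_returns_one_auc_per_repetition(cohort20):
    config = _fast_config(modes=("None",), repetitions=3)
    aucs = run_naive_split(cohort20, config, test_fraction=1 / 3, mode="None")
    assert len(aucs) == 3
    assert all(0.0 <= a <= 1.0 for a in aucs)


def test_summarize_fields(cohort20):
    res = run_experiment(cohort20, _fast_config(modes=("None",)))
    s = summarize(res["None"])
    assert s["n_repetitions"] == 2
    assert s["range_cv_auc"][0] <= s["mean_cv_auc"] <= s["range_cv_auc"][1]
    assert s["ci95_cv_auc"][0] <= s["mean_cv_auc"] <= s["ci95_cv_auc"][1]
    assert s["setting"] == "CHSQ+LASSO+LR"


def test_unknown_mode_rejected():
    with pytest.raises(ValueError, match="unknown modes"):
        _fast_config(modes=("IAFA", "bogus"))
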