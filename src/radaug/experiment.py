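"""Orchestration of repeated cross-validation with dual-level augmentation.

Four ablation modes are compared on identical fold plans:

* ``None`` — plain stratified CV;
* ``FA``   — SMOTE balancing of the training folds in feature space;
* ``IA``   — image-level augmentation of the training cases (original + 9
  copies) before feature extraction, followed by the ICC >= 0.9
  reproducibility gate;
* ``IAFA`` — IA, then the ICC gate, then SMOTE.

Test folds always receive preprocessing + extraction only; no augmented or
synthetic row ever has a parent in the test fold.  Image augmentations are
drawn once per (repetition, case) and reused across the training folds of
that repetition; they are re-randomized across repetitions, as are the fold
assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from radaug.augment import AugmentationRecipe, run_ia_recipe
from radaug.classifiers import fit_predict
from radaug.cv import FoldPlan, auc, cv_auc, make_fold_plan, mean_auc, youden_metrics
from radaug.features.extract import FeatureTable, extract_table
from radaug.features.preprocess import PreprocessConfig
from radaug.features.schema import ExtractionProfile
from radaug.grid import PipelineSetting
from radaug.icc import filter_reproducible
from radaug.smote import SmoteConfig, smote_oversample
from radaug.types import INTENSITY_OPS, VolumeCase

logger = logging.getLogger(__name__)

MODES = ("None", "FA", "IA", "IAFA")


@dataclass(frozen=True)
class ExperimentConfig:
    setting: PipelineSetting
    modes: Tuple[str, ...] = MODES
    k: int = 3
    repetitions: int = 10
    recipe: AugmentationRecipe = AugmentationRecipe()
    preprocess: PreprocessConfig = PreprocessConfig()
    profile: ExtractionProfile = field(default_factory=ExtractionProfile.light)
    smote_k: int = 5
    smote_directions: object = "auto"
    icc_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")


@dataclass
class TrialResult:
    """Metrics of one repetition of one setting under one ablation mode."""

    setting: str
    mode: str
    repetition: int
    fold_aucs: List[float]
    mean_auc: float
    cv_auc: float
    cv_sensitivity: float
    cv_specificity: float
    selected: List[List[str]]
    seed: int


def _mode_uses_ia(mode: str) -> bool:
    return mode in ("IA", "IAFA")


def _mode_uses_fa(mode: str) -> bool:
    return mode in ("FA", "IAFA")


def _augmented_table(
    cases: Sequence[VolumeCase],
    config: ExperimentConfig,
    case_seeds: Sequence[int],
) -> Tuple[FeatureTable, set]:
    aug_cases = []
    for case, s in zip(cases, case_seeds):
        aug_cases.extend(run_ia_recipe(case, config.recipe, s))
    intensity_ids = {a.case_id for a in aug_cases if a.op_kind in INTENSITY_OPS}
    return extract_table(aug_cases, config.preprocess, config.profile), intensity_ids


def _run_fold(
    base: FeatureTable,
    aug: Optional[FeatureTable],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    mode: str,
    config: ExperimentConfig,
    smote_seed: int,
    model_seed: int,
    intensity_ids: Optional[set] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Fit one training fold under one mode; return (probs, labels, selected)."""
    train_tab = base.subset_rows(train_ids)
    if _mode_uses_ia(mode):
        assert aug is not None and intensity_ids is not None
        aug_rows = aug.parent_id.index[aug.parent_id.isin(train_ids)]
        feats = pd.concat([train_tab.features, aug.features.loc[aug_rows]])
        labels = pd.concat([train_tab.labels, aug.labels.loc[aug_rows]])
        parents = pd.concat([train_tab.parent_id, aug.parent_id.loc[aug_rows]])
        train_tab = FeatureTable(feats, labels, parents)
        # reproducibility gate: agreement across the original + intensity-op
        # copies (morphological copies are genuinely different geometries)
        gate_rows = [i for i in train_tab.features.index if i in intensity_ids or i in train_ids]
        cols = filter_reproducible(
            FeatureTable(train_tab.features.loc[gate_rows], train_tab.labels.loc[gate_rows],
                         train_tab.parent_id.loc[gate_rows]),
            config.icc_threshold,
        )
        train_tab = train_tab.subset_columns(cols)
    else:
        cols = train_tab.columns

    x_tr = train_tab.features.to_numpy(dtype=float)
    y_tr = train_tab.labels.to_numpy()
    if _mode_uses_fa(mode):
        x_tr, y_tr, _ = smote_oversample(
            x_tr, y_tr, SmoteConfig(k_neighbors=config.smote_k, directions_per_sample=config.smote_directions, seed=smote_seed)
        )

    test_tab = base.subset_rows(test_ids).subset_columns(cols)
    probs, sel_idx = fit_predict(
        config.setting, x_tr, y_tr, test_tab.features.to_numpy(dtype=float), seed=model_seed
    )
    selected = [cols[i] for i in sel_idx]
    return probs, test_tab.labels.to_numpy(), selected


def run_experiment(
    cohort: Sequence[VolumeCase],
    config: ExperimentConfig,
    base_table: Optional[FeatureTable] = None,
) -> Dict[str, List[TrialResult]]:
    """Run all requested modes over the repeated fold plan.

    ``base_table`` may carry precomputed original-case features (they are
    mode-independent); otherwise they are extracted here.
    """
    labels = [c.label for c in cohort]
    ids = [c.case_id for c in cohort]
    root = np.random.SeedSequence(config.seed)
    ss_folds, ss_reps = root.spawn(2)
    fold_plan = make_fold_plan(labels, config.k, config.repetitions, int(ss_folds.generate_state(1)[0] % (2**31)))
    if base_table is None:
        base_table = extract_table(cohort, config.preprocess, config.profile)

    rep_children = ss_reps.spawn(config.repetitions)
    needs_ia = any(_mode_uses_ia(m) for m in config.modes)
    results: Dict[str, List[TrialResult]] = {m: [] for m in config.modes}

    for r in range(config.repetitions):
        ss_ia, ss_smote, ss_model = rep_children[r].spawn(3)
        aug_table, intensity_ids = None, None
        if needs_ia:
            case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_ia.spawn(len(cohort))]
            aug_table, intensity_ids = _augmented_table(cohort, config, case_seeds)
        smote_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_smote.spawn(config.k)]
        model_seed = int(ss_model.generate_state(1)[0] % (2**31))

        fold_members = [
            [ids[i] for i in np.flatnonzero(fold_plan.assignment[r] == f)] for f in range(config.k)
        ]
        for mode in config.modes:
            fold_probs, fold_labels, fold_sel, fold_aucs = [], [], [], []
            try:
                for f in range(config.k):
                    test_ids = fold_members[f]
                    train_ids = [i for i in ids if i not in test_ids]
                    probs, y_te, selected = _run_fold(
                        base_table, aug_table, train_ids, test_ids, mode, config,
                        smote_seeds[f], model_seed, intensity_ids,
                    )
                    fold_probs.append(probs)
                    fold_labels.append(y_te)
                    fold_sel.append(selected)
                    fold_aucs.append(auc(probs, y_te))
            except ValueError as exc:
                logger.warning("trial failed (mode %s, repetition %d): %s", mode, r, exc)
                continue
            pooled_p = np.concatenate(fold_probs)
            pooled_l = np.concatenate(fold_labels)
            sens, spec, _ = youden_metrics(pooled_p, pooled_l)
            results[mode].append(
                TrialResult(
                    setting=config.setting.name,
                    mode=mode,
                    repetition=r,
                    fold_aucs=fold_aucs,
                    mean_auc=mean_auc(fold_aucs),
                    cv_auc=cv_auc(fold_probs, fold_labels),
                    cv_sensitivity=sens,
                    cv_specificity=spec,
                    selected=fold_sel,
                    seed=config.seed,
                )
            )
    return results


def run_naive_split(
    cohort: Sequence[VolumeCase],
    config: ExperimentConfig,
    test_fraction: float,
    mode: str = "None",
    base_table: Optional[FeatureTable] = None,
) -> List[float]:
    """Naive stratified train-test splits (e.g. 2:1, 4:1, 9:1); returns per-repetition AUCs.

    Demonstrates the split-to-split variability that motivates pooled
    repeated CV.
    """
    from sklearn.model_selection import train_test_split

    labels = np.asarray([c.label for c in cohort])
    ids = np.asarray([c.case_id for c in cohort])
    if base_table is None:
        base_table = extract_table(cohort, config.preprocess, config.profile)
    root = np.random.SeedSequence(config.seed)
    out = []
    for r, child in enumerate(root.spawn(config.repetitions)):
        s1, s2, s3 = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)]
        train_ids, test_ids = train_test_split(
            ids, test_size=test_fraction, stratify=labels, random_state=s1
        )
        aug_table, intensity_ids = None, None
        if _mode_uses_ia(mode):
            case_by_id = {c.case_id: c for c in cohort}
            train_cases = [case_by_id[i] for i in train_ids]
            seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(s2).spawn(len(train_cases))]
            aug_table, intensity_ids = _augmented_table(train_cases, config, seeds)
        probs, y_te, _ = _run_fold(base_table, aug_table, list(train_ids), list(test_ids), mode, config, s2, s3, intensity_ids)
        out.append(auc(probs, y_te))
    return out


def ablation_config(seed: int = 0, repetitions: int = 10, k: int = 3) -> ExperimentConfig:
    """The standard ablation-trend experiment configuration.

    Reduced grid (CHSQ + LASSO + LR), K=3, small-volume augmentation
    magnitudes, and the original-filter extraction profile (all seven
    feature classes on the unfiltered image, 214 features for two
    sequences), sized so repeated CV over four modes completes in minutes
    on one CPU.
    """
    return ExperimentConfig(
        setting=PipelineSetting("CHSQ", "LASSO", "LR"),
        modes=MODES,
        k=k,
        repetitions=repetitions,
        recipe=AugmentationRecipe.small_volume(),
        profile=ExtractionProfile.original_filter(),
        seed=seed,
    )


def summarize(results: Sequence[TrialResult]) -> Dict[str, object]:
    """Best-trial and distributional summary of one mode's repetitions."""
    cv_aucs = np.array([t.cv_auc for t in results])
    best = results[int(np.argmax(cv_aucs))]
    n = len(cv_aucs)
    se = cv_aucs.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return {
        "setting": best.setting,
        "mode": best.mode,
        "best_repetition": best.repetition,
        "best_cv_auc": float(best.cv_auc),
        "best_mean_auc": float(best.mean_auc),
        "best_cv_sensitivity": float(best.cv_sensitivity),
        "best_cv_specificity": float(best.cv_specificity),
        "mean_cv_auc": float(cv_aucs.mean()),
        "ci95_cv_auc": [float(cv_aucs.mean() - 1.96 * se), float(cv_aucs.mean() + 1.96 * se)],
        "range_cv_auc": [float(cv_aucs.min()), float(cv_aucs.max())],
        "n_repetitions": n,
    }
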