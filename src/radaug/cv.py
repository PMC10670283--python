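"""Repeated stratified k-fold plans and ROC metrics.

The headline metric is the pooled CV-AUC: a single AUC computed on the
concatenated held-out predictions of all K folds of one repetition — not
the mean of the per-fold AUCs, which is also provided.  The operating
point for sensitivity/specificity maximizes the Youden index
(sensitivity + specificity - 1) over observed score cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class FoldPlan:
    """repetition x case fold assignment, stratified, seeded per repetition."""

    k: int
    repetitions: int
    assignment: np.ndarray  # (repetitions, n_cases) fold ids
    seed: int

    @property
    def n_cases(self) -> int:
        return self.assignment.shape[1]


def make_fold_plan(labels: Sequence[int], k: int, repetitions: int, seed: int) -> FoldPlan:
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError(f"K={k} exceeds the minority class count {counts.min()}; stratification impossible")
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(repetitions)]
    assignment = np.zeros((repetitions, len(labels)), dtype=int)
    for r, rs in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignment[r, test_idx] = fold_id
    return FoldPlan(k=k, repetitions=repetitions, assignment=assignment, seed=seed)


def auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties contribute 1/2."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a single-class prediction set")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


def mean_auc(per_fold_aucs: Sequence[float]) -> float:
    return float(np.mean(per_fold_aucs))


def cv_auc(fold_probs: Sequence[np.ndarray], fold_labels: Sequence[np.ndarray]) -> float:
    """Single AUC on the pooled predictions of all folds of one repetition."""
    return auc(np.concatenate([np.asarray(p) for p in fold_probs]),
               np.concatenate([np.asarray(l) for l in fold_labels]))


def youden_metrics(probs: Sequence[float], labels: Sequence[int]) -> Tuple[float, float, float]:
    """(sensitivity, specificity, threshold) at the maximal Youden index.

    Thresholds scan the observed scores (prediction positive when
    prob >= threshold); ties go to the lowest such threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes required")
    best = (-np.inf, 0.0, 0.0, 0.0)
    for t in np.sort(np.unique(probs)):
        pred = probs >= t
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & ~pos).sum() / (~pos).sum())
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, sens, spec, float(t))
    return best[1], best[2], best[3]
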