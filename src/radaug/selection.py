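"""Two-level feature selection.

First level (filter methods): univariate or multivariate relevance scores;
features are ranked and the top ``first_level_keep`` retained.  Second
level (embedded methods): sparse-penalized linear models tuned along their
regularization path to at most ``max_selected`` nonzero coefficients, or
tree-ensemble importances truncated to the top ``max_selected``.
"""

from __future__ import annotations

import logging
from typing import List, Tuple

import numpy as np
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression, enet_path, lasso_path
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


def _bin_nonneg(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Min-shift and bin each feature (chi-square needs non-negative input)."""
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        rng = col.max() - col.min()
        out[:, j] = np.floor((col - col.min()) / (rng / n_bins + 1e-12)).clip(0, n_bins - 1) if rng > 0 else 0.0
    return out


def _relief_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Relief margin: mean |x - nearest miss| - |x - nearest hit| per feature."""
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    scores = np.zeros(x.shape[1])
    for i in range(len(z)):
        same = y == y[i]
        same[i] = False
        if not same.any() or same.all():
            continue
        hit = np.argmin(np.where(same, d2[i], np.inf))
        miss = np.argmin(np.where(~same, d2[i], np.inf))
        scores += np.abs(z[i] - z[miss]) - np.abs(z[i] - z[hit])
    return scores / len(z)


def _mrmr_order(x: np.ndarray, y: np.ndarray, keep: int) -> Tuple[np.ndarray, np.ndarray]:
    """Greedy minimum-redundancy maximum-relevance ordering.

    Relevance is the one-way F statistic against the label; redundancy is
    the mean absolute Pearson correlation with already-selected features
    (F-statistic quotient variant).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        rel, _ = f_classif(x, y)
    rel = np.nan_to_num(rel, nan=0.0, posinf=0.0)
    sd = x.std(axis=0)
    varying = sd > 0
    corr = np.zeros((x.shape[1], x.shape[1]))
    if varying.sum() >= 2:
        sub = np.corrcoef(x[:, varying], rowvar=False)
        corr[np.ix_(varying, varying)] = np.abs(np.nan_to_num(sub))
    selected: List[int] = []
    remaining = list(range(x.shape[1]))
    scores = np.zeros(x.shape[1])
    while remaining and len(selected) < min(keep, x.shape[1]):
        if not selected:
            best = remaining[int(np.argmax(rel[remaining]))]
            scores[best] = rel[best]
        else:
            red = corr[np.ix_(remaining, selected)].mean(axis=1)
            quot = rel[remaining] / (red + 1e-6)
            best = remaining[int(np.argmax(quot))]
            scores[best] = quot[int(np.argmax(quot))]
        selected.append(best)
        remaining.remove(best)
    order = np.array(selected + remaining)
    return order, scores


def rank_first_level(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    keep: int = 100,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rank features by the given filter method; return (top indices, scores).

    Constant features score 0 and are never ranked above varying features.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature matrix")
    n_feat = x.shape[1]
    varying = x.std(axis=0) > 0
    scores = np.zeros(n_feat)

    if method == "CHSQ":
        s, _ = sk_chi2(_bin_nonneg(x), y)
        scores = np.nan_to_num(s, nan=0.0)
    elif method == "TSQ":
        a, b = x[y == 0], x[y == 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, _ = stats.ttest_ind(a, b, axis=0)
        scores = np.abs(np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0))
    elif method == "KWH":
        for j in np.flatnonzero(varying):
            try:
                scores[j] = stats.kruskal(x[y == 0, j], x[y == 1, j]).statistic
            except ValueError:
                scores[j] = 0.0
        scores = np.nan_to_num(scores, nan=0.0)
    elif method == "VAR":
        scores = x.var(axis=0)
    elif method == "RELF":
        scores = _relief_scores(x, y)
    elif method == "MI":
        scores = mutual_info_classif(x, y, random_state=seed)
    elif method == "mRMRe":
        order, scores = _mrmr_order(x, y, keep)
        order = order[varying[order]][:keep] if varying.any() else order[:keep]
        return order, scores
    else:
        raise ValueError(f"unknown filter method {method!r}")

    scores[~varying] = 0.0
    order = np.argsort(-scores, kind="stable")
    order = order[varying[order]] if varying.any() else order
    return order[:keep], scores


def _path_select(coef_path: np.ndarray, max_selected: int) -> np.ndarray:
    """Pick the path point with the largest support not exceeding max_selected.

    This is the least-regularized admissible penalty: the final subset size
    sits just under the cap, matching the regime in which the two-level
    screen is meant to operate.
    """
    nnz = (np.abs(coef_path) > 1e-10).sum(axis=0)
    ok = np.flatnonzero(nnz <= max_selected)
    if len(ok) == 0:
        return np.array([], dtype=int)
    best = ok[np.argmax(nnz[ok])]
    return np.flatnonzero(np.abs(coef_path[:, best]) > 1e-10)


def _c_grid_select(estimator_factory, x, y, max_selected) -> np.ndarray:
    best: np.ndarray = np.array([], dtype=int)
    for c in np.logspace(-3, 2, 16):
        est = estimator_factory(c)
        est.fit(x, y)
        coef = est.coef_.ravel()
        idx = np.flatnonzero(np.abs(coef) > 1e-8)
        if len(idx) <= max_selected and len(idx) > len(best):
            best = idx
    return best


def select_second_level(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    max_selected: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Embedded selection on first-level-screened features.

    Returns indices into the columns of ``x``; an empty selection falls
    back to the single first column (the top first-level feature), logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd

    yc = y.astype(float) - y.mean()
    if method == "LASSO":
        _, coefs, _ = lasso_path(xs, yc)
        idx = _path_select(coefs, max_selected)
    elif method == "EN":
        _, coefs, _ = enet_path(xs, yc, l1_ratio=0.5)
        idx = _path_select(coefs, max_selected)
    elif method == "L1-LR":
        idx = _c_grid_select(
            lambda c: LogisticRegression(penalty="l1", solver="liblinear", C=c, max_iter=200, random_state=seed),
            xs, y, max_selected,
        )
    elif method == "L1-SVM":
        idx = _c_grid_select(
            lambda c: LinearSVC(penalty="l1", dual=False, C=c, max_iter=3000, random_state=seed),
            xs, y, max_selected,
        )
    elif method in ("RF", "ETE", "GBDT", "XGB"):
        if method == "RF":
            est = RandomForestClassifier(n_estimators=100, random_state=seed)
        elif method == "ETE":
            est = ExtraTreesClassifier(n_estimators=100, random_state=seed)
        elif method == "GBDT":
            est = GradientBoostingClassifier(random_state=seed)
        else:
            from xgboost import XGBClassifier

            est = XGBClassifier(n_estimators=100, random_state=seed, verbosity=0, eval_metric="logloss")
        est.fit(xs, y)
        imp = est.feature_importances_
        idx = np.argsort(-imp, kind="stable")[:max_selected]
        idx = idx[imp[idx] > 0]
    else:
        raise ValueError(f"unknown embedded method {method!r}")

    if len(idx) == 0:
        logger.info("embedded method %s selected nothing; falling back to top-ranked feature", method)
        idx = np.array([0])
    return np.sort(idx)
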