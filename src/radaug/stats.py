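"""Statistical comparison of settings.

* DeLong's test for two correlated ROC AUCs on the same cases, via the
  structural-components (pseudovalue) estimate of the variance of the
  paired AUC difference.
* Two-sided paired t-test on per-repetition metric series.
* Linear trend test across the ordered modes None -> FA -> IA -> IAFA:
  a within-repetition least-squares slope of the metric on the mode rank
  (0..3), then a one-sample two-sided t-test of the slopes against zero.

Significance threshold alpha = 0.05 throughout; no multiplicity correction.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats


def _structural_components(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # one per positive case
    v01 = cmp.mean(axis=0)  # one per negative case
    return v10, v01, float(cmp.mean())


def delong_test(probs_a: Sequence[float], probs_b: Sequence[float], labels: Sequence[int]) -> Tuple[float, float, float]:
    """Two-sided DeLong comparison of two correlated AUCs.

    Returns (auc_a, auc_b, p_value).  Both score vectors must refer to the
    same cases in the same order.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if not (len(a) == len(b) == len(y)):
        raise ValueError("score vectors and labels must have equal length")

    v10_a, v01_a, auc_a = _structural_components(a, y)
    v10_b, v01_b, auc_b = _structural_components(b, y)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def paired_ttest(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value; all-zero differences give p = 1."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired series with >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    return float(stats.ttest_rel(a, b).pvalue)


def trend_test(series_per_mode: Sequence[Sequence[float]]) -> float:
    """Linear trend across ordered modes; see module docstring.

    ``series_per_mode`` is one aligned per-repetition series per mode, in
    trend order (e.g. None, FA, IA, IAFA).
    """
    mat = np.asarray(series_per_mode, dtype=float)  # (modes, repetitions)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need >= 2 repetitions of aligned mode series")
    ranks = np.arange(mat.shape[0], dtype=float)
    ranks_c = ranks - ranks.mean()
    slopes = (ranks_c @ mat) / (ranks_c @ ranks_c)  # per-repetition OLS slope
    scale = max(np.abs(mat).max(), 1.0)
    if np.allclose(slopes, slopes[0], atol=1e-12 * scale):
        if abs(slopes[0]) < 1e-12 * scale:
            return 1.0
        return 0.0  # identical nonzero slopes: infinite t limit
    return float(stats.ttest_1samp(slopes, 0.0).pvalue)
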