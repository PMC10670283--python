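"""Feature reproducibility across augmented replicates: ICC(2,1) gate.

The intraclass correlation used here is the two-way random-effects,
absolute-agreement, single-measurement coefficient, computed from the
classical mean-squares decomposition of a cases x replicates grid:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n cases (rows), k replicates (columns), MSR the between-row, MSC the
between-column and MSE the residual mean square.  Features whose ICC across
the original + augmented copies of each training case falls below the
threshold (default 0.9) are dropped before feature-level augmentation.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np

logger = logging.getLogger(__name__)


def _mean_squares(values: np.ndarray):
    n, k = values.shape[:2]
    grand = values.mean(axis=(0, 1))
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((values - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(values) -> float:
    """ICC(2,1) of one cases x replicates grid."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2D cases x replicates grid")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 cases and >= 2 replicates")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing or non-finite values")
    if np.ptp(values) == 0:
        return 1.0  # all values identical (identical per case in particular)
    msr, msc, mse = _mean_squares(values[:, :, None])
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom[0] == 0:
        if np.all(values == values[:, :1]):
            return 1.0
        raise ValueError("zero total variance with non-identical replicates")
    return float(((msr - mse) / denom)[0])


def icc_matrix(values: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over a cases x replicates x features array."""
    n, k, _ = values.shape
    msr, msc, mse = _mean_squares(values)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (msr - mse) / denom
    flat = np.ptp(values.reshape(n * k, -1), axis=0) == 0
    out[flat] = 1.0
    return out


def filter_reproducible(table, threshold: float = 0.9) -> List[str]:
    """Columns of a replicate-grouped feature table with ICC >= threshold.

    ``table`` is a FeatureTable whose rows group by ``parent_id``; every
    parent must contribute the same number of replicate rows (original +
    augmented copies).  Constant features are excluded through the
    zero-variance path and logged.  Raising the threshold never adds
    features; if nothing passes, an explicit error aborts the trial.
    """
    groups = table.parent_id.groupby(table.parent_id).size()
    if (groups < 2).any():
        raise ValueError("every parent case needs >= 2 replicates")
    if groups.nunique() != 1:
        raise ValueError("unbalanced replicate counts across parent cases")
    k = int(groups.iloc[0])
    n = len(groups)
    if n < 2:
        raise ValueError("need >= 2 parent cases")

    order = np.argsort(table.parent_id.to_numpy(), kind="stable")
    vals = table.features.to_numpy(dtype=float)[order].reshape(n, k, -1)

    constant = np.ptp(vals.reshape(n * k, -1), axis=0) == 0
    iccs = icc_matrix(vals)
    keep_mask = (iccs >= threshold) & ~constant
    if constant.any():
        logger.info("excluded %d constant features via the zero-variance path", int(constant.sum()))
    keep = [c for c, ok in zip(table.columns, keep_mask) if ok]
    if not keep:
        raise ValueError("no feature passed the reproducibility filter (empty schema)")
    return keep
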