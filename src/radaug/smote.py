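"""Feature-level augmentation: SMOTE oversampling of the minority class.

New minority samples are interpolated on the segment between a minority
sample and one of its k nearest minority-class neighbors:

    x_new = x_i + u * (x_nbr - x_i),   u ~ Uniform(0, 1)

Oversampling continues in rounds (one synthetic sample per minority case
per round, a different neighbor direction each round) until the minority
count equals the majority count exactly; the last round is truncated by
drawing a uniform subset of minority parents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    directions_per_sample: Union[int, str] = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.directions_per_sample != "auto" and not (
            0 <= int(self.directions_per_sample) <= self.k_neighbors
        ):
            raise ValueError("need k_neighbors >= directions_per_sample >= 0")


def minority_neighbors(x_minority: np.ndarray, k: int) -> np.ndarray:
    """Euclidean k-nearest neighbors within the minority class, self excluded.

    Distance ties break toward the lower index.  If fewer than k+1 samples
    exist, k is reduced with a warning.
    """
    x = np.asarray(x_minority, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 minority samples")
    if n - 1 < k:
        warnings.warn(f"only {n - 1} neighbors available; reducing k from {k}")
        k = n - 1
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")  # stable: ties -> lower index
    return order[:, :k]


@dataclass
class SyntheticProvenance:
    parent: int
    neighbor: int
    u: float


def smote_oversample(
    x: np.ndarray,
    y: np.ndarray,
    config: SmoteConfig = SmoteConfig(),
) -> Tuple[np.ndarray, np.ndarray, List[SyntheticProvenance]]:
    """Balance the two classes exactly 1:1 by synthesizing minority rows.

    Returns (x_balanced, y_balanced, provenance); the input rows come first,
    synthetic rows are appended.  An already-balanced input is returned
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    needed = int(n_maj - n_min)
    if needed == 0:
        return x, y, []
    if n_min < 2:
        raise ValueError("need >= 2 minority samples for SMOTE")

    rng = np.random.default_rng(config.seed)
    min_idx = np.flatnonzero(y == minority)
    x_min = x[min_idx]
    nbrs = minority_neighbors(x_min, config.k_neighbors)
    k_eff = nbrs.shape[1]

    if config.directions_per_sample == "auto":
        directions = int(np.ceil(needed / n_min))
    else:
        directions = int(config.directions_per_sample)
        if directions == 0:
            raise ValueError("cannot balance with 0 directions per sample")

    synth_rows, prov = [], []
    produced = 0
    rounds = int(np.ceil(needed / n_min))
    for r in range(rounds):
        remaining = needed - produced
        parents = np.arange(n_min)
        if remaining < n_min:  # truncated last round: uniform subset of parents
            parents = rng.choice(n_min, size=remaining, replace=False)
        for i in parents:
            j = nbrs[i, rng.integers(min(directions, k_eff))] if k_eff > 1 else nbrs[i, 0]
            u = rng.uniform()
            synth_rows.append(x_min[i] + u * (x_min[j] - x_min[i]))
            prov.append(SyntheticProvenance(parent=int(min_idx[i]), neighbor=int(min_idx[j]), u=float(u)))
            produced += 1

    x_out = np.vstack([x, np.asarray(synth_rows)])
    y_out = np.concatenate([y, np.full(needed, minority, dtype=int)])
    assert (y_out == minority).sum() == n_maj
    return x_out, y_out, prov
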