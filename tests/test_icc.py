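"""ICC(2,1) against a brute-force ANOVA oracle and the reproducibility gate."""

import numpy as np
import pandas as pd
import pytest

from radaug.icc import filter_reproducible, icc, icc_matrix
from radaug.features.extract import FeatureTable


def anova_icc_oracle(grid):
    """Independent mean-squares decomposition with explicit loops."""
    grid = np.asarray(grid, dtype=float)
    n, k = grid.shape
    grand = grid.mean()
    msr = k * sum((grid[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((grid[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (grid[i, j] - grid[i].mean() - grid[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_perfect_agreement_gives_one():
    grid = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
    assert icc(grid) == pytest.approx(1.0)


def test_pure_noise_gives_near_zero(rng):
    grids = [rng.normal(size=(40, 5)) for _ in range(20)]
    vals = [icc(g) for g in grids]
    assert abs(np.mean(vals)) < 0.1


def test_matches_anova_oracle_on_random_grids(rng):
    for _ in range(20):
        grid = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1)) * 2
        assert icc(grid) == pytest.approx(anova_icc_oracle(grid), abs=1e-12)


def test_matches_pingouin_reference():
    """Cross-check ICC(2,1) against the published statistics package."""
    import pingouin as pg

    rng = np.random.default_rng(11)
    grid = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 1.5
    n, k = grid.shape
    df = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "val": grid.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="case", raters="rater", ratings="val")
    icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert icc(grid) == pytest.approx(icc2, abs=1e-9)


def test_known_variance_ratio_closed_form(rng):
    """case-variance 4, replicate-noise variance sigma^2: ICC -> 4/(4+s^2)."""
    n, k = 400, 6
    for sigma, target in [(0.5, 4 / 4.25), (2.0, 4 / 8.0)]:
        grid = 2.0 * rng.normal(size=(n, 1)) + sigma * rng.normal(size=(n, k))
        assert icc(grid) == pytest.approx(target, abs=0.06)


def test_vectorized_matches_scalar(rng):
    vals = rng.normal(size=(5, 3, 7))
    many = icc_matrix(vals)
    for f in range(7):
        assert many[f] == pytest.approx(icc(vals[:, :, f]), abs=1e-12)


def test_input_validation():
    with pytest.raises(ValueError):
        icc(np.ones((1, 5)))
    with pytest.raises(ValueError):
        icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


def _table(values: np.ndarray, n_cases: int, k: int, columns):
    ids = [f"c{i}_r{j}" for i in range(n_cases) for j in range(k)]
    parents = [f"c{i}" for i in range(n_cases) for j in range(k)]
    df = pd.DataFrame(values, index=ids, columns=columns)
    return FeatureTable(df, pd.Series(0, index=ids), pd.Series(parents, index=ids))


def test_filter_keeps_exactly_the_stable_half(rng):
    """Features with tiny replicate noise pass at 0.9; noisy ones fail."""
    n, k = 30, 4
    case_effect = rng.normal(size=(n, 1, 1)) * 3.0
    stable = case_effect + 0.1 * rng.normal(size=(n, k, 5))
    noisy = case_effect + 5.0 * rng.normal(size=(n, k, 5))
    vals = np.concatenate([stable, noisy], axis=2).reshape(n * k, 10)
    cols = [f"stable{i}" for i in range(5)] + [f"noisy{i}" for i in range(5)]
    table = _table(vals, n, k, cols)
    kept = filter_reproducible(table, threshold=0.9)
    assert kept == cols[:5]


def test_filter_threshold_monotone(rng):
    n, k = 20, 4
    case_effect = np.repeat(rng.normal(size=(n, 1)) * 2, k, axis=0)
    vals = case_effect + rng.normal(size=(n * k, 8)) * np.linspace(0.05, 3, 8)
    table = _table(vals, n, k, [f"f{i}" for i in range(8)])
    kept_low = set(filter_reproducible(table, threshold=-1.0))
    kept_mid = set(filter_reproducible(table, threshold=0.7))
    kept_high = set(filter_reproducible(table, threshold=0.95))
    assert kept_high <= kept_mid <= kept_low


def test_vacuous_threshold_keeps_all_varying(rng):
    n, k = 10, 3
    vals = rng.normal(size=(n * k, 4))
    table = _table(vals, n, k, list("abcd"))
    assert filter_reproducible(table, threshold=-1.0) == list("abcd")


def test_constant_feature_excluded(rng):
    n, k = 10, 3
    vals = rng.normal(size=(n * k, 3))
    vals[:, 1] = 7.0
    table = _table(vals, n, k, list("abc"))
    kept = filter_reproducible(table, threshold=-1.0)
    assert "b" not in kept


def test_nothing_passes_raises(rng):
    n, k = 10, 3
    vals = np.full((n * k, 2), 3.14)
    table = _table(vals, n, k, list("ab"))
    with pytest.raises(ValueError, match="no feature passed"):
        filter_reproducible(table, threshold=0.9)
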