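"""Index construction: kinship log-sum, KMO adequacy, first-PC friendship index."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strongties.indices import (
    FRIENDSHIP_INDICATORS,
    clan_indicator,
    friend_frequency,
    friendship_index,
    kinship_index,
    kmo,
)


def exact_correlation_design(n: int, R: np.ndarray, seed: int = 0) -> np.ndarray:
    """n x p matrix whose *sample* correlation matrix equals R exactly.

    Draws Gaussian data, empirically whitens it, then recolors with the
    Cholesky factor of R — a deterministic design, not an estimate.
    """
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    cov = (X.T @ X) / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T  # exact identity covariance
    return X @ np.linalg.cholesky(R).T


def equicorrelation(p: int, rho: float) -> np.ndarray:
    return (1 - rho) * np.eye(p) + rho * np.ones((p, p))


# ------------------------------------------------------------- kinship


def test_kinship_index_values():
    assert kinship_index([0.0] * 5, [0.0] * 5) == 0.0
    give = [math.e - 1.0, 0, 0, 0, 0]
    assert kinship_index(give, [0.0] * 5) == pytest.approx(1.0, abs=1e-12)
    amounts = np.array([500_000, 400_000, 200_000, 100_000, 9_427.0])
    total = amounts.sum()
    assert total == 1_209_427
    got = kinship_index(amounts, [0.0] * 5)
    assert got == pytest.approx(math.log(1 + total), abs=1e-12)
    assert 14.0 < got < 14.01  # totals of this magnitude give indices ~14


def test_kinship_index_rejects_negative_amounts():
    with pytest.raises(ValueError, match="nonnegative"):
        kinship_index([-1.0, 0, 0, 0, 0], [0.0] * 5)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    amounts=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=10, max_size=10),
    j=st.integers(0, 9),
    bump=st.floats(0, 1e6, allow_nan=False),
)
def test_kinship_index_monotone_in_every_amount(amounts, j, bump):
    base = np.asarray(amounts)
    more = base.copy()
    more[j] += bump
    assert kinship_index(more[None, :]) >= kinship_index(base[None, :])


# ----------------------------------------------------------------- KMO


def test_kmo_equicorrelated_closed_form():
    """rho = 0.5 on 3 variables: KMO = 0.75 / (0.75 + 3*(1/3)^2) = 9/13."""
    X = exact_correlation_design(200, equicorrelation(3, 0.5), seed=1)
    diag = kmo(X)
    assert diag.kmo_overall == pytest.approx(0.75 / (0.75 + 3 * (1 / 3) ** 2), abs=1e-10)
    # symmetric design: identical per-item MSA
    assert np.allclose(diag.kmo_per_item, diag.kmo_per_item[0], atol=1e-10)


def test_kmo_orthogonal_design_is_zero_with_warning():
    X = exact_correlation_design(100, np.eye(3), seed=2)
    with pytest.warns(RuntimeWarning, match="KMO reported as 0"):
        diag = kmo(X)
    assert diag.kmo_overall == 0.0


def _kmo_oracle(X: np.ndarray) -> float:
    """Independent textbook KMO: partial correlations via OLS residuals."""
    p = X.shape[1]
    R = np.corrcoef(X, rowvar=False)
    P = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            Z = np.column_stack([np.ones(len(X)), X[:, others]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            P[i, j] = P[j, i] = np.corrcoef(ri, rj)[0, 1]
    off = ~np.eye(p, dtype=bool)
    return (R[off] ** 2).sum() / ((R[off] ** 2).sum() + (P[off] ** 2).sum())


@pytest.mark.parametrize("trial", range(20))
def test_kmo_matches_partial_correlation_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    p = rng.integers(3, 7)
    n = int(rng.integers(50, 200))
    # random factor structure so correlations are nontrivial
    L = rng.normal(size=(p, 2))
    F = rng.standard_normal((n, 2))
    X = F @ L.T + rng.standard_normal((n, p))
    assert kmo(X).kmo_overall == pytest.approx(_kmo_oracle(X), abs=1e-10)


def test_kmo_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="constant indicator"):
        kmo(np.column_stack([np.ones(50), rng.standard_normal((50, 2))]))
    with pytest.raises(ValueError, match=">= 3 columns"):
        kmo(rng.standard_normal((50, 2)))


# ---------------------------------------------------- friendship index


def test_friendship_index_normalization(population):
    X = population[FRIENDSHIP_INDICATORS].astype(float)
    scores, diag = friendship_index(X)
    assert diag.proportions.sum() == pytest.approx(1.0, abs=1e-10)
    assert diag.cumulative[-1] == pytest.approx(1.0, abs=1e-10)
    assert diag.eigenvalues.sum() == pytest.approx(3.0, abs=1e-10)
    assert np.all(np.diff(diag.cumulative) >= 0)
    assert abs(scores.mean()) <= 1e-8
    assert scores.std(ddof=1) > 0
    assert diag.n_retained >= 1
    # loadings are orthonormal eigenvectors of the correlation matrix
    assert np.allclose(diag.loadings @ diag.loadings.T, np.eye(3), atol=1e-10)
    # sign convention: social spending loads positively on the first PC
    assert diag.loadings[0, 0] > 0


def test_friendship_index_affine_invariance(population):
    X = population[FRIENDSHIP_INDICATORS].astype(float).to_numpy()
    scores, _ = friendship_index(X)
    Y = X.copy()
    Y[:, 1] = 1000.0 * Y[:, 1] + 37.0  # unit change absorbed by standardization
    scores2, _ = friendship_index(Y)
    assert np.allclose(scores, scores2, atol=1e-8)


def test_friendship_index_iid_indicators_eigenvalue_one(rng):
    """Independent indicators: all three eigenvalues near 1; agree with an
    independent eigensolver."""
    X = rng.standard_normal((5000, 3))
    _, diag = friendship_index(X)
    assert diag.eigenvalues[0] == pytest.approx(1.0, abs=0.1)
    # independent oracle: SVD of the standardized data
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    sv = np.linalg.svd(Z / np.sqrt(len(X) - 1), compute_uv=False)
    assert np.allclose(np.sort(sv**2)[::-1], diag.eigenvalues, atol=1e-8)


def test_friendship_index_rejects_degenerate_input():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError):
        friendship_index(rng.standard_normal((2, 3)))
    X = rng.standard_normal((100, 3))
    X[:, 2] = 5.0
    with pytest.raises(ValueError, match="constant"):
        friendship_index(X)


# ------------------------------------------------- robustness variants


def test_clan_indicator_values():
    assert clan_indicator([0.0] * 10) == 0.0
    assert clan_indicator([0, 0, 0, 0.01, 0, 0, 0, 0, 0, 0]) == 1.0
    with pytest.raises(ValueError, match="nonnegative"):
        clan_indicator([-5.0] + [0.0] * 9)


def test_clan_share_matches_calibration():
    from strongties import GeneratorConfig, generate_population
    from strongties.indices import TRANSFER_COLUMNS

    n = 20_000
    df = generate_population(GeneratorConfig(n=n, seed=21))
    share = clan_indicator(df[TRANSFER_COLUMNS].astype(float)).mean()
    se = math.sqrt(0.546 * 0.454 / n)
    assert abs(share - 0.546) < 3 * se


def test_friend_frequency_bounds():
    assert friend_frequency(0) == 0
    assert friend_frequency(6) == 6
    with pytest.raises(ValueError, match=r"\[0, 6\]"):
        friend_frequency(7)
    with pytest.raises(ValueError):
        friend_frequency(-1)
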