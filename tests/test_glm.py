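"""Maximum-likelihood estimator: closed forms, oracles, invariances, errors."""

import numpy as np
import pandas as pd
import pytest

from strongties.glm import (
    ModelSpec,
    RankDeficiencyError,
    SeparationError,
    fit_binary,
)


def two_by_two_frame(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """x=1: a successes / b failures; x=0: c successes / d failures."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1] * (a + b) + [0] * (c + d)
    return pd.DataFrame({"y": y, "x": x})


def oracle_loglike_logit(y, X, beta):
    eta = X @ beta
    return np.sum(y * eta - np.log1p(np.exp(eta)))


def grid_search_mle(y, X, lo=-5.0, hi=5.0, points=41, refinements=8):
    """Brute-force likelihood maximizer over a refining 2-D grid."""
    assert X.shape[1] == 2
    c0 = (lo + hi) / 2, (lo + hi) / 2
    half = (hi - lo) / 2
    best = None
    for _ in range(refinements):
        g0 = np.linspace(c0[0] - half, c0[0] + half, points)
        g1 = np.linspace(c0[1] - half, c0[1] + half, points)
        ll = np.array([[oracle_loglike_logit(y, X, np.array([b0, b1])) for b1 in g1]
                       for b0 in g0])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0 = (g0[i], g1[j])
        best = np.array(c0)
        half = 3 * (g0[1] - g0[0])
    return best


def test_intercept_only_balanced_outcome():
    df = pd.DataFrame({"y": [0, 1] * 50})
    fit = fit_binary(df, ModelSpec("y", ()))
    assert abs(fit.coef[0]) < 1e-10
    assert fit.odds_ratios[0] == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("cells", [(40, 60, 25, 75), (13, 7, 11, 19), (80, 20, 30, 70)])
def test_two_by_two_odds_ratio_is_cross_product_ratio(cells):
    a, b, c, d = cells
    fit = fit_binary(two_by_two_frame(a, b, c, d), ModelSpec("y", ("x",)))
    assert fit.odds_ratios[1] == pytest.approx(a * d / (b * c), abs=1e-10)


def test_ml_matches_brute_force_grid_search():
    rng = np.random.default_rng(5)
    n = 50
    x = rng.standard_normal(n)
    eta = -0.4 + 0.9 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame({"y": y, "x": x})
    fit = fit_binary(df, ModelSpec("y", ("x",)))
    X = np.column_stack([np.ones(n), x])
    beta_grid = grid_search_mle(y, X)
    assert np.allclose(fit.coef, beta_grid, atol=1e-4)


@pytest.mark.parametrize("link", ["logit", "probit"])
def test_matches_statsmodels(link, indexed):
    sm = pytest.importorskip("statsmodels.api")
    df = indexed.head(800)
    spec = ModelSpec("care_all", ("hosnet_R", "age", "insurance"), link)
    fit = fit_binary(df, spec)
    X = sm.add_constant(df[list(spec.regressors)].astype(float))
    y = df["care_all"].astype(float)
    model = sm.Logit(y, X) if link == "logit" else sm.Probit(y, X)
    ref = model.fit(disp=0)
    assert np.allclose(fit.coef, ref.params.to_numpy(), atol=1e-6)
    assert np.allclose(fit.se, ref.bse.to_numpy(), atol=1e-5)
    assert fit.llf == pytest.approx(ref.llf, abs=1e-6)


def test_affine_rescaling_of_regressor_rescales_coefficient(indexed):
    spec = ModelSpec("care_all", ("age", "hosnet_R"))
    fit = fit_binary(indexed, spec)
    scaled = indexed.copy()
    scaled["age"] = scaled["age"] / 10.0
    fit2 = fit_binary(scaled, spec)
    assert fit2.coef[1] == pytest.approx(10.0 * fit.coef[1], rel=1e-7)
    assert fit2.llf == pytest.approx(fit.llf, abs=1e-8)


def test_pseudo_r2_ordering_and_null(indexed):
    fit = fit_binary(indexed, ModelSpec("care_all", ("hosnet_R", "age")))
    assert fit.pseudo_r2_adj <= fit.pseudo_r2 < 1
    # a pure-noise regressor explains ~nothing
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"y": rng.integers(0, 2, 4000), "x": rng.standard_normal(4000)})
    fit0 = fit_binary(df, ModelSpec("y", ("x",)))
    assert abs(fit0.pseudo_r2_adj) < 0.01


def test_z_statistics_and_stars(indexed):
    fit = fit_binary(indexed, ModelSpec("care_all", ("age",)))
    assert np.allclose(fit.zvalues, fit.coef / fit.se)
    assert all(s in ("", "*", "**", "***") for s in fit.stars())


def test_perfect_separation_raises():
    x = np.concatenate([-np.abs(np.random.default_rng(1).standard_normal(50)) - 0.1,
                        np.abs(np.random.default_rng(2).standard_normal(50)) + 0.1])
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_binary(pd.DataFrame({"y": y, "x": x}), ModelSpec("y", ("x",)))


def test_rank_deficiency_names_collinear_column(indexed):
    df = indexed.copy()
    df["age_twice"] = 2.0 * df["age"].astype(float)
    with pytest.raises(RankDeficiencyError, match="age_twice"):
        fit_binary(df, ModelSpec("care_all", ("age", "age_twice")))
    df["flat"] = 1.0
    with pytest.raises(RankDeficiencyError, match="flat"):
        fit_binary(df, ModelSpec("care_all", ("flat",)))


def test_outcome_validation(indexed):
    df = indexed.head(100).copy()
    df["const_y"] = 1
    with pytest.raises(ValueError, match="single class"):
        fit_binary(df, ModelSpec("const_y", ("age",)))
    df["bad_y"] = 2
    with pytest.raises(ValueError, match="coded 0/1"):
        fit_binary(df, ModelSpec("bad_y", ("age",)))


def test_listwise_deletion_reduces_n(indexed):
    df = indexed.copy()
    df.loc[df.index[:50], "l_expen"] = np.nan
    fit = fit_binary(df, ModelSpec("care_all", ("l_expen",)))
    assert fit.n_used == len(df) - 50
    # refit on identical data reproduces identical estimates
    fit2 = fit_binary(df, ModelSpec("care_all", ("l_expen",)))
    assert np.array_equal(fit.coef, fit2.coef)


def test_probit_logit_sign_concordance_and_scale():
    """On the same data, probit and logit agree in sign for moderate effects,
    and logit coefficients are ~1.6x the probit ones."""
    from strongties import GeneratorConfig, generate_population
    from strongties.indices import build_index_bundle

    terms = ("hosnet_R", "age", "insurance", "province")
    logit_means = np.zeros(len(terms) + 1)
    probit_means = np.zeros(len(terms) + 1)
    n_rep = 20
    for rep in range(n_rep):
        df, _ = build_index_bundle(
            generate_population(GeneratorConfig(n=4000, seed=500 + rep))
        )
        f_l = fit_binary(df, ModelSpec("care_all", terms, "logit"))
        f_p = fit_binary(df, ModelSpec("care_all", terms, "probit"))
        assert np.all(np.sign(f_l.coef[1:]) == np.sign(f_p.coef[1:]))
        logit_means += f_l.coef / n_rep
        probit_means += f_p.coef / n_rep
    ratio = logit_means[1:] / probit_means[1:]
    assert np.all(np.abs(ratio - 1.6) < 0.15 * 1.6)
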