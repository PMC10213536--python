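"""Binary-choice maximum likelihood and the care-model regression batteries.

The estimator is a Newton-Raphson maximiser of the logit / probit
log-likelihood with observed-information standard errors, listwise deletion
of missing values, rank and separation diagnostics, and McFadden (adjusted)
pseudo-R².  Logit fits report odds ratios ``exp(coef)``; probit fits report
raw coefficients.

Batteries mirror the study design on the respondent table:

* ``baseline_battery``   — kinship / friendship index, bare and with the
  ten controls (four fits);
* ``robustness_battery`` — replacement regressors (clan, friend) under
  logit and the original indices under probit (four fits);
* ``heterogeneity_battery`` — east/mid-west and urban/rural subsamples for
  each index (eight fits);
* ``mechanism_battery``  — per index: index -> supplementary medical
  insurance, then care choice on medical + index, then the same on the
  healthy subsample (three fits per index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "ModelSpec",
    "BinaryFit",
    "SeparationError",
    "RankDeficiencyError",
    "fit_binary",
    "baseline_battery",
    "robustness_battery",
    "heterogeneity_battery",
    "mechanism_battery",
    "battery_frame",
    "render_battery",
    "CONTROLS",
]

#: the ten controls: personal, family and regional characteristics
CONTROLS = [
    "age",
    "gender",
    "edu",
    "married",
    "health",
    "insurance",
    "l_expen",
    "family",
    "urban",
    "province",
]

_MAX_ITER = 100
_SCORE_TOL = 1e-10  # max-norm of the score at convergence
_SEPARATION_BOUND = 20.0  # |coef| on the standardized scale


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE diverges."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class ModelSpec:
    """A single binary-choice model: outcome, ordered regressors, link.

    ``subgroup`` optionally restricts the sample, either as a
    ``(column, value)`` pair or a row predicate.
    """

    outcome: str
    regressors: tuple[str, ...]
    link: str = "logit"
    subgroup: tuple[str, object] | Callable[[pd.DataFrame], pd.Series] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.link not in ("logit", "probit"):
            raise ValueError(f"link must be 'logit' or 'probit', got {self.link!r}")
        object.__setattr__(self, "regressors", tuple(self.regressors))


@dataclass
class BinaryFit:
    """Estimation result of one binary-choice model."""

    spec: ModelSpec
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    odds_ratios: np.ndarray | None
    llf: float
    ll_null: float
    n_used: int
    converged: bool
    iterations: int
    label: str = ""
    cov: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def pseudo_r2(self) -> float:
        """McFadden pseudo-R²: 1 - LL/LL0."""
        return 1.0 - self.llf / self.ll_null

    @property
    def pseudo_r2_adj(self) -> float:
        """McFadden adjusted pseudo-R²: 1 - (LL - k)/LL0, k = n parameters."""
        k = len(self.coef)
        return 1.0 - (self.llf - k) / self.ll_null

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])

    def stars(self) -> list[str]:
        return [_stars(p) for p in self.pvalues]

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
                "stars": self.stars(),
            },
            index=self.names,
        )
        if self.odds_ratios is not None:
            df.insert(0, "odds_ratio", self.odds_ratios)
        return df


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def _loglike_logit(y, X, beta):
    eta = X @ beta
    # log L = sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _loglike_probit(y, X, beta):
    eta = X @ beta
    q = 2.0 * y - 1.0
    return float(np.sum(log_ndtr(q * eta)))


def loglike(y, X, beta, link: str) -> float:
    """Log-likelihood of a binary model at ``beta`` (used by test oracles too)."""
    return _loglike_logit(y, X, beta) if link == "logit" else _loglike_probit(y, X, beta)


def _score_hessian(y, X, beta, link):
    eta = X @ beta
    if link == "logit":
        p = expit(eta)
        g = X.T @ (y - p)
        w = p * (1.0 - p)
    else:
        q = 2.0 * y - 1.0
        pdf = stats.norm.pdf(eta)
        s = q * pdf / ndtr(q * eta)
        g = X.T @ s
        w = s * (s + eta)  # observed information weights
    H = -(X.T * w) @ X
    return g, H


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # name a minimal set of columns whose removal restores full rank
    bad: list[str] = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            bad.append(names[j])
    raise RankDeficiencyError(
        f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
        f"collinear column(s): {bad}"
    )


def fit_binary(table: pd.DataFrame, spec: ModelSpec) -> BinaryFit:
    """Newton-Raphson maximum-likelihood fit of a binary logit/probit model.

    Listwise deletion over the model's variables; requires both outcome
    classes and a full-rank design.  Raises :class:`SeparationError` when
    coefficients diverge (|standardized coef| > 20 with a non-vanishing
    score) and :class:`RankDeficiencyError` naming collinear columns.
    Non-convergence within 100 iterations returns a flagged partial result.
    """
    cols = [spec.outcome, *spec.regressors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    df = table
    if spec.subgroup is not None:
        if callable(spec.subgroup):
            mask = spec.subgroup(df)
        else:
            col, val = spec.subgroup
            if df[col].nunique(dropna=True) < 2:
                raise ValueError(
                    f"subgroup column {col!r} is constant; cannot split on it"
                )
            mask = df[col] == val
        df = df.loc[mask]
    df = df[cols].dropna()
    n_used = len(df)
    y = df[spec.outcome].to_numpy(dtype=float)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"outcome {spec.outcome!r} must be coded 0/1, got {uniq}")
    if uniq.size < 2:
        raise ValueError(
            f"outcome {spec.outcome!r} has a single class after listwise deletion"
        )
    Xr = df[list(spec.regressors)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n_used), Xr])
    names = ["const", *spec.regressors]
    for j, nm in enumerate(spec.regressors, start=1):
        if np.all(X[:, j] == X[0, j]):
            raise RankDeficiencyError(
                f"design matrix is rank deficient; collinear column(s): [{nm!r}] (constant)"
            )
    _check_rank(X, names)

    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0  # intercept
    ybar = y.mean()
    beta = np.zeros(X.shape[1])
    beta[0] = (
        np.log(ybar / (1 - ybar)) if spec.link == "logit" else stats.norm.ppf(ybar)
    )
    ll = loglike(y, X, beta, spec.link)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        g, H = _score_hessian(y, X, beta, spec.link)
        if np.max(np.abs(g)) <= _SCORE_TOL:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular Hessian during Newton iteration (likely separation)"
            ) from exc
        # damped Newton: halve until the likelihood does not decrease
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            ll_new = loglike(y, X, cand, spec.link)
            if ll_new >= ll - 1e-13:
                break
            lam *= 0.5
        beta = cand
        ll = ll_new
        if np.max(np.abs(beta) * scale) > _SEPARATION_BOUND:
            g2, _ = _score_hessian(y, X, beta, spec.link)
            if np.max(np.abs(g2)) > 1e-4:
                raise SeparationError(
                    "coefficients diverging (|standardized coef| > "
                    f"{_SEPARATION_BOUND}); data are (quasi-)separated"
                )
    g, H = _score_hessian(y, X, beta, spec.link)
    if np.max(np.abs(g)) <= _SCORE_TOL:
        converged = True
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ors = np.exp(beta) if spec.link == "logit" else None
    ll_null = _null_loglike(y, spec.link)
    return BinaryFit(
        spec=spec,
        names=names,
        coef=beta,
        se=se,
        zvalues=z,
        pvalues=pvals,
        odds_ratios=ors,
        llf=ll,
        ll_null=ll_null,
        n_used=n_used,
        converged=converged,
        iterations=it,
        label=spec.label,
        cov=cov,
    )


def _null_loglike(y: np.ndarray, link: str) -> float:
    p = y.mean()
    # intercept-only MLE is the sample mean under either link
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


# ---------------------------------------------------------------- batteries


def baseline_battery(table: pd.DataFrame) -> list[BinaryFit]:
    """Four baseline logit fits: each index bare, then with all controls."""
    specs = [
        ModelSpec("care_all", ("hosnet_R",), "logit", label="kinship (1)"),
        ModelSpec("care_all", ("hosnet_R", *CONTROLS), "logit", label="kinship (2)"),
        ModelSpec("care_all", ("hosnet_F",), "logit", label="friendship (1)"),
        ModelSpec("care_all", ("hosnet_F", *CONTROLS), "logit", label="friendship (2)"),
    ]
    return [fit_binary(table, s) for s in specs]


def robustness_battery(table: pd.DataFrame) -> list[BinaryFit]:
    """Replacement regressors under logit; original indices under probit."""
    specs = [
        ModelSpec("care_all", ("clan", *CONTROLS), "logit", label="logit clan"),
        ModelSpec("care_all", ("friend", *CONTROLS), "logit", label="logit friend"),
        ModelSpec("care_all", ("hosnet_R", *CONTROLS), "probit", label="probit hosnet_R"),
        ModelSpec("care_all", ("hosnet_F", *CONTROLS), "probit", label="probit hosnet_F"),
    ]
    return [fit_binary(table, s) for s in specs]


def heterogeneity_battery(table: pd.DataFrame) -> list[BinaryFit]:
    """Eight subgroup fits: {east, mid-west} x {urban, rural} per index.

    The split dummy is dropped from the controls inside its own subgroups
    (it is constant there).
    """
    fits = []
    for index in ("hosnet_R", "hosnet_F"):
        for split_col, val, name in [
            ("province", 1, "east"),
            ("province", 0, "mid-west"),
            ("urban", 1, "urban"),
            ("urban", 0, "rural"),
        ]:
            controls = tuple(c for c in CONTROLS if c != split_col)
            spec = ModelSpec(
                "care_all",
                (index, *controls),
                "logit",
                subgroup=(split_col, val),
                label=f"{index} | {name}",
            )
            fits.append(fit_binary(table, spec))
    return fits


def mechanism_battery(table: pd.DataFrame) -> dict[str, list[BinaryFit]]:
    """Mediation-style triple per index.

    (1) medical ~ index + controls  — does the tie index raise take-up of
        supplementary medical insurance?
    (2) care_all ~ medical + index + controls — does medical insurance in
        turn raise formal-care choice?
    (3) model (2) restricted to the healthy (health == 1) subsample, where
        own disability risk cannot drive the association.
    """
    if "medical" not in table.columns:
        raise KeyError("mechanism battery requires a 'medical' column")
    out: dict[str, list[BinaryFit]] = {}
    for index in ("hosnet_R", "hosnet_F"):
        healthy_controls = tuple(c for c in CONTROLS if c != "health")
        specs = [
            ModelSpec("medical", (index, *CONTROLS), "logit", label=f"medical (1) [{index}]"),
            ModelSpec(
                "care_all", ("medical", index, *CONTROLS), "logit",
                label=f"care_all (2) [{index}]",
            ),
            ModelSpec(
                "care_all", ("medical", index, *healthy_controls), "logit",
                subgroup=("health", 1), label=f"care_all (3) [{index}, healthy]",
            ),
        ]
        out[index] = [fit_binary(table, s) for s in specs]
    return out


# ------------------------------------------------------------- rendering


def battery_frame(fits: Sequence[BinaryFit]) -> pd.DataFrame:
    """Long-format table of a battery: one row per (model, regressor)."""
    rows = []
    for f in fits:
        for i, name in enumerate(f.names):
            rows.append(
                {
                    "model": f.label or f.spec.label,
                    "link": f.spec.link,
                    "term": name,
                    "coef": f.coef[i],
                    "odds_ratio": f.odds_ratios[i] if f.odds_ratios is not None else np.nan,
                    "se": f.se[i],
                    "z": f.zvalues[i],
                    "p": f.pvalues[i],
                    "stars": _stars(f.pvalues[i]),
                    "n": f.n_used,
                    "pseudo_r2_adj": f.pseudo_r2_adj,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)


def render_battery(fits: Sequence[BinaryFit], title: str = "") -> str:
    """Aligned plain-text regression table.

    Logit columns show odds ratios, probit columns raw coefficients, each
    with the Wald z statistic in parentheses and significance stars at the
    10/5/1% levels; sample size and adjusted pseudo-R² in the footer.
    """
    terms: list[str] = []
    for f in fits:
        for name in f.names:
            if name not in terms:
                terms.append(name)
    headers = [f.label or f"model {i+1}" for i, f in enumerate(fits)]
    width = max(18, *(len(h) + 2 for h in headers))
    lines = []
    if title:
        lines.append(title)
    lines.append("".join(["term".ljust(16)] + [h.rjust(width) for h in headers]))
    for term in terms:
        cells = []
        for f in fits:
            if term in f.names:
                i = f.names.index(term)
                val = f.odds_ratios[i] if f.odds_ratios is not None else f.coef[i]
                cells.append(f"{val:.4g}{_stars(f.pvalues[i])} ({f.zvalues[i]:.2f})")
            else:
                cells.append("-")
        lines.append("".join([term.ljust(16)] + [c.rjust(width) for c in cells]))
    lines.append(
        "".join(["n".ljust(16)] + [f"{f.n_used}".rjust(width) for f in fits])
    )
    lines.append(
        "".join(
            ["adj pseudo-R2".ljust(16)]
            + [f"{f.pseudo_r2_adj:.4f}".rjust(width) for f in fits]
        )
    )
    lines.append("stars: * p<0.10, ** p<0.05, *** p<0.01 (two-sided Wald)")
    return "\n".join(lines)
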