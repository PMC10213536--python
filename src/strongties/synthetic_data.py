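"""Synthetic CHARLS-like survey microdata with a known data-generating process.

One row per respondent aged 45+, with the variables the care-choice
analysis needs: five give/receive economic-transfer pairs to relative
categories, three friendship indicators (ceremonial/catering spending,
guest person-meals last week, social-activity count last month), a 0-6
social-contact frequency, ten controls, a supplementary-medical-insurance
indicator ``medical`` and the binary care-model outcome ``care_all``
(1 = formal home/community care chosen).

The generating process inverts cleanly under the downstream pipeline:

1. covariates are drawn from marginals calibrated to the source survey's
   descriptive statistics (first moments only);
2. transfers are zero-inflated log-normal per category, calibrated so the
   kinship index ``ln(1 + total)`` has mean ~1.496 with ~45.4% exact zeros;
3. the friendship indicators share a weak latent sociability factor, so
   their correlation structure (and hence the first-PC eigenvalue ~1.06)
   mirrors the survey's;
4. ``medical`` is Bernoulli-logistic in the friendship index (the mediation
   channel), and ``care_all`` is Bernoulli-logistic in the *derived* kinship
   index, the ten controls and ``medical`` — the same formulas the
   :mod:`strongties.indices` module applies — so refitting the true model on
   generated data recovers the configured coefficients.

Default true odds ratios are the study's headline estimates (kinship index
1.091, age 1.036, insurance 1.736, province 1.318, medical 1.823, ...),
with the intercept set so formal-care prevalence is ~0.1975.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .indices import FRIENDSHIP_INDICATORS, TRANSFER_COLUMNS, friendship_index, kinship_index

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "ParseError",
    "generate_population",
    "write_table",
    "read_table",
    "COLUMN_ORDER",
    "COLUMN_DTYPES",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class ParseError(ValueError):
    """Malformed delimited table; message names the line and column."""


#: fixed output column order of the respondent table
COLUMN_ORDER = [
    "id",
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
    *TRANSFER_COLUMNS,
    *FRIENDSHIP_INDICATORS,
    "contact_freq",
    "medical",
    "care_all",
]

#: dtype contract: Int64 (nullable) for counts/binaries, float64 for amounts
COLUMN_DTYPES: dict[str, str] = {
    "id": "Int64",
    "age": "Int64",
    "gender": "Int64",
    "edu": "Int64",
    "married": "Int64",
    "health": "Int64",
    "insurance": "Int64",
    "l_expen": "float64",
    "family": "Int64",
    "urban": "Int64",
    "province": "Int64",
    **{c: "float64" for c in TRANSFER_COLUMNS},
    "social_spend": "float64",
    "guest_meals": "Int64",
    "social_activity": "Int64",
    "contact_freq": "Int64",
    "medical": "Int64",
    "care_all": "Int64",
}

# target means of the binary covariates and (mean, sd) of the continuous ones
_DEFAULT_COVARIATE_PARAMS: dict[str, object] = {
    "gender": 0.4730,
    "edu": 0.1269,
    "married": 0.8508,
    "health": 0.2501,
    "insurance": 0.9697,
    "urban": 0.2888,
    "province": 0.3090,
    "l_expen": (7.1346, 1.0272),
    # household size: Poisson mean (source survey subgroup means ~3.05-3.08),
    # clipped to [0, 20]
    "family": 3.07,
    # age: truncated normal on [45, 121]; parent-normal (mu, sigma) solved so
    # the truncated moments match mean 64.8572 / sd 10.2065
    "age": (63.6135, 11.3521, 45.0, 121.0),
}

# zero-inflated log-normal transfers: P(category inactive), log-mean, log-sd.
# p_zero^10 = 0.454 reproduces the any-transfer share 0.546; the log-mean is
# solved so E[ln(1 + total)] ~ 1.4961.
_DEFAULT_TRANSFER_PARAMS: dict[str, float] = {
    "p_zero": 0.9240715,
    "log_mean": 1.9970,
    "log_sd": 2.0,
}

# friendship indicators: weak shared latent factor (loading w) plus
# idiosyncratic noise; marginals give the heavy-tailed spending and small
# counts typical of the survey
_DEFAULT_FRIENDSHIP_PARAMS: dict[str, float] = {
    "latent_loading": 0.25,
    "spend_p_active": 0.65,
    "spend_log_mean": 6.5,
    "spend_log_sd": 1.3,
    "meals_log_rate": 0.5,
    "meals_latent_scale": 0.5,
    "activity_log_rate": -0.3,
    "activity_latent_scale": 0.5,
    "contact_log_rate": -0.7584,
    "contact_latent_scale": 0.9,
}

# true log-odds of the care_all model; exp() of these are the headline odds
# ratios. Intercept solved so prevalence ~0.1975 at the covariate defaults.
_DEFAULT_TRUE_LOGIT_COEFS: dict[str, float] = {
    "const": -4.7575,
    "hosnet_R": float(np.log(1.091)),
    "age": float(np.log(1.036)),
    "gender": float(np.log(1.048)),
    "edu": float(np.log(0.914)),
    "married": float(np.log(0.881)),
    "health": float(np.log(1.069)),
    "insurance": float(np.log(1.736)),
    "l_expen": float(np.log(1.032)),
    "family": float(np.log(1.010)),
    "urban": float(np.log(1.007)),
    "province": float(np.log(1.318)),
    "medical": float(np.log(1.823)),
}

# medical ~ friendship index (the mediation channel); intercept gives
# take-up ~0.12
_DEFAULT_MEDIATION_COEFS: dict[str, float] = {
    "const": -1.9886,
    "hosnet_F": float(np.log(1.082)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Sample size, seed and the true data-generating parameters.

    ``true_logit_coefs`` keys are ``const``, regressor column names, and
    optionally ``a:b`` interaction keys (coefficient on the product of two
    columns, used e.g. for subgroup-specific effects).  ``missing_rate`` is
    a global per-field missingness probability or a per-field dict.
    """

    n: int = 20_000
    seed: int = 0
    covariate_params: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATE_PARAMS))
    transfer_params: dict = field(default_factory=lambda: dict(_DEFAULT_TRANSFER_PARAMS))
    friendship_params: dict = field(default_factory=lambda: dict(_DEFAULT_FRIENDSHIP_PARAMS))
    true_logit_coefs: dict = field(default_factory=lambda: dict(_DEFAULT_TRUE_LOGIT_COEFS))
    mediation_coefs: dict = field(default_factory=lambda: dict(_DEFAULT_MEDIATION_COEFS))
    missing_rate: float | dict = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n <= 0:
            raise ConfigError(f"generator.n must be a positive integer, got {self.n!r}")
        pz = self.transfer_params.get("p_zero", 0.0)
        if not 0.0 <= pz <= 1.0:
            raise ConfigError(f"transfer p_zero must be in [0, 1], got {pz!r}")
        valid = set(COLUMN_ORDER) | {"const", "hosnet_R", "hosnet_F", "clan", "friend"}
        for coefs, label in ((self.true_logit_coefs, "true_logit_coefs"),
                             (self.mediation_coefs, "mediation_coefs")):
            for key in coefs:
                parts = key.split(":")
                bad = [p for p in parts if p != "const" and p not in valid]
                if bad:
                    raise ConfigError(
                        f"{label} names unknown regressor(s) {bad} in key {key!r}"
                    )
        rates = (
            self.missing_rate.values()
            if isinstance(self.missing_rate, dict)
            else [self.missing_rate]
        )
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ConfigError("missing_rate values must be in [0, 1)")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


def _linear_predictor(coefs: dict, frame: pd.DataFrame) -> np.ndarray:
    lp = np.zeros(len(frame))
    for key, c in coefs.items():
        term = np.ones(len(frame))
        for part in key.split(":"):
            if part != "const":
                term = term * frame[part].to_numpy(dtype=float)
        lp += c * term
    return lp


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a respondent table of exactly ``config.n`` rows.

    Deterministic in ``(config, seed)``.  The outcome ``care_all`` is
    Bernoulli with logistic probability in the derived indices (computed
    internally with the same formulas as :mod:`strongties.indices`), the
    controls and ``medical``; ``medical`` is drawn first from the
    friendship-index mediation model.
    """
    n = config.n
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_params
    tp = config.transfer_params
    fp = config.friendship_params

    z = rng.standard_normal(n)  # latent sociability factor

    mu_a, sd_a, lo_a, hi_a = cov["age"]
    a, b = (lo_a - mu_a) / sd_a, (hi_a - mu_a) / sd_a
    age = stats.truncnorm.rvs(a, b, loc=mu_a, scale=sd_a, size=n, random_state=rng)
    age = np.clip(np.rint(age), lo_a, hi_a).astype(np.int64)

    df = pd.DataFrame({"id": np.arange(1, n + 1, dtype=np.int64)})
    df["age"] = age
    for name in ("gender", "edu", "married", "health", "insurance", "urban", "province"):
        df[name] = (rng.random(n) < cov[name]).astype(np.int64)
    m_le, sd_le = cov["l_expen"]
    df["l_expen"] = rng.normal(m_le, sd_le, size=n)
    df["family"] = np.minimum(rng.poisson(cov["family"], size=n), 20).astype(np.int64)

    log_mean = np.broadcast_to(np.asarray(tp["log_mean"], dtype=float), (10,))
    log_sd = np.broadcast_to(np.asarray(tp["log_sd"], dtype=float), (10,))
    active = rng.random((n, 10)) >= tp["p_zero"]
    amounts = np.exp(rng.normal(log_mean, log_sd, size=(n, 10)))
    amounts = np.round(amounts, 2) * active
    for j, col in enumerate(TRANSFER_COLUMNS):
        df[col] = amounts[:, j]

    w = fp["latent_loading"]
    noise = rng.standard_normal((n, 4))
    u = w * z[:, None] + np.sqrt(1.0 - w * w) * noise
    spend_active = rng.random(n) < fp["spend_p_active"]
    spend = np.round(np.exp(fp["spend_log_mean"] + fp["spend_log_sd"] * u[:, 0]), 2)
    df["social_spend"] = np.where(spend_active, spend, 0.0)
    df["guest_meals"] = rng.poisson(
        np.exp(fp["meals_log_rate"] + fp["meals_latent_scale"] * u[:, 1])
    ).astype(np.int64)
    df["social_activity"] = rng.poisson(
        np.exp(fp["activity_log_rate"] + fp["activity_latent_scale"] * u[:, 2])
    ).astype(np.int64)
    df["contact_freq"] = np.minimum(
        rng.poisson(np.exp(fp["contact_log_rate"] + fp["contact_latent_scale"] * u[:, 3])),
        6,
    ).astype(np.int64)

    # derived indices, exactly as the downstream indices module computes them
    derived = pd.DataFrame(index=df.index)
    derived["hosnet_R"] = kinship_index(df[TRANSFER_COLUMNS])
    if n >= 4:
        scores, _ = friendship_index(df[FRIENDSHIP_INDICATORS])
        derived["hosnet_F"] = scores
    else:  # PCA needs more rows than indicators; tiny samples get no channel
        derived["hosnet_F"] = 0.0
    frame = pd.concat([df, derived], axis=1)

    lp_med = _linear_predictor(config.mediation_coefs, frame)
    medical = (rng.random(n) < _expit(lp_med)).astype(np.int64)
    df["medical"] = medical
    frame["medical"] = medical

    lp = _linear_predictor(config.true_logit_coefs, frame)
    df["care_all"] = (rng.random(n) < _expit(lp)).astype(np.int64)

    df = df[COLUMN_ORDER].astype(COLUMN_DTYPES)

    if _any_missing(config.missing_rate):
        maskable = [c for c in COLUMN_ORDER if c != "id"]
        for col in maskable:
            r = (
                config.missing_rate.get(col, 0.0)
                if isinstance(config.missing_rate, dict)
                else config.missing_rate
            )
            if r > 0:
                df.loc[rng.random(n) < r, col] = pd.NA
    return df


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def _any_missing(missing_rate) -> bool:
    if isinstance(missing_rate, dict):
        return any(v > 0 for v in missing_rate.values())
    return missing_rate > 0


# ------------------------------------------------------------------- I/O


def write_table(table: pd.DataFrame, path) -> None:
    """Write a table as CSV: one header row, empty fields for missing values."""
    table.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring the dtype contract.

    Columns named in :data:`COLUMN_DTYPES` get their contracted dtype; other
    columns are converted to the best numeric type, falling back to strings.
    Malformed numeric fields raise :class:`ParseError` naming line and column.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed delimited file {path}: {exc}") from exc
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        s = raw[col].replace("", None)
        target = COLUMN_DTYPES.get(col)
        try:
            if target is not None:
                out[col] = _convert(s, target)
            else:
                try:
                    out[col] = pd.to_numeric(s)
                except (ValueError, TypeError):
                    out[col] = s
        except (ValueError, TypeError) as exc:
            bad = _first_bad_line(s, target or "float64")
            raise ParseError(
                f"column {col!r}, line {bad}: cannot parse value "
                f"{raw[col].iloc[bad - 2]!r} as {target}"
            ) from exc
    return out


def _convert(s: pd.Series, target: str) -> pd.Series:
    num = pd.to_numeric(s)
    return num.astype(target)


def _first_bad_line(s: pd.Series, target: str) -> int:
    for i, v in enumerate(s):
        if v is None:
            continue
        try:
            float(v)
        except (ValueError, TypeError):
            return i + 2  # 1-based, after the header line
    return 2


def table_to_csv_bytes(table: pd.DataFrame) -> bytes:
    """CSV rendering as bytes (used for checksums and byte-identity checks)."""
    buf = io.StringIO()
    write_table(table, buf)
    return buf.getvalue().encode()
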