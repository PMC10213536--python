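"""Strong-social-tie regressors: kinship and friendship composite indices.

Two composite indices operationalise "strong social ties" in survey
microdata:

* the kinship index ``hosnet_R = ln(1 + total transfers)``, the log of the
  summed give/receive economic transfers across five relative categories
  (zero exactly when no money changed hands, heavy right tail otherwise);
* the friendship index ``hosnet_F``, the first principal component of three
  standardized social-interaction indicators (ceremonial/catering spending,
  guest person-meals last week, social-activity count last month), retained
  by the eigenvalue >= 1 rule after a Kaiser-Meyer-Olkin adequacy check.

Robustness variants: ``clan`` (any-transfer dummy) and ``friend`` (social
contact frequency on a 0-6 scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PCADiagnostics",
    "kinship_index",
    "kmo",
    "friendship_index",
    "clan_indicator",
    "friend_frequency",
    "build_index_bundle",
    "FRIENDSHIP_INDICATORS",
    "TRANSFER_COLUMNS",
]

#: give/receive transfer columns, five relative categories each
TRANSFER_COLUMNS = [f"transfer_give_{k}" for k in range(1, 6)] + [
    f"transfer_receive_{k}" for k in range(1, 6)
]

#: friendship indicators in fixed order; the first anchors the PC sign
FRIENDSHIP_INDICATORS = ["social_spend", "guest_meals", "social_activity"]


@dataclass
class PCADiagnostics:
    """KMO and correlation-matrix PCA diagnostics for a composite index.

    ``eigenvalues`` descend and sum to the number of indicators;
    ``proportions`` sum to 1; ``n_retained`` counts eigenvalues >= 1,
    floored at 1.  ``loadings`` has one row per component (orthonormal
    eigenvectors of the correlation matrix).
    """

    kmo_overall: float
    kmo_per_item: np.ndarray
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    loadings: np.ndarray
    n_retained: int
    indicator_names: list[str] = field(default_factory=list)

    def report_lines(self) -> list[str]:
        """Key-value rendering of the diagnostics (adequacy + scree table)."""
        lines = [f"kmo_overall\t{self.kmo_overall:.6f}"]
        for name, v in zip(self.indicator_names, self.kmo_per_item):
            lines.append(f"kmo_item_{name}\t{v:.6f}")
        for i, (ev, pr, cu) in enumerate(
            zip(self.eigenvalues, self.proportions, self.cumulative), start=1
        ):
            lines.append(f"comp{i}\teigenvalue={ev:.6f}\tproportion={pr:.6f}\tcumulative={cu:.6f}")
        lines.append(f"n_retained\t{self.n_retained}")
        return lines


def _as_transfer_matrix(give, receive=None) -> np.ndarray:
    if receive is not None:
        arr = np.column_stack(
            [np.atleast_2d(np.asarray(give, dtype=float)),
             np.atleast_2d(np.asarray(receive, dtype=float))]
        )
    else:
        arr = np.atleast_2d(np.asarray(give, dtype=float))
    return arr


def kinship_index(transfers_give, transfers_receive=None):
    """Kinship index: ``ln(1 + sum of all give and receive amounts)``.

    Accepts one row (two length-5 vectors or one length-10 vector) or a
    2-D array / DataFrame of rows; returns a scalar or a vector.  Amounts
    must be nonnegative; NaN amounts propagate to a NaN index.
    """
    if isinstance(transfers_give, pd.DataFrame):
        arr = transfers_give.to_numpy(dtype=float)
    else:
        arr = _as_transfer_matrix(transfers_give, transfers_receive)
    with np.errstate(invalid="ignore"):
        if np.any(arr < 0):
            raise ValueError("transfer amounts must be nonnegative")
    total = arr.sum(axis=1)
    out = np.log1p(total)
    return float(out[0]) if out.shape[0] == 1 and np.ndim(transfers_give) <= 1 else out


def clan_indicator(transfers_give, transfers_receive=None):
    """Any-transfer dummy: 1 iff total economic transactions > 0."""
    if isinstance(transfers_give, pd.DataFrame):
        arr = transfers_give.to_numpy(dtype=float)
    else:
        arr = _as_transfer_matrix(transfers_give, transfers_receive)
    with np.errstate(invalid="ignore"):
        if np.any(arr < 0):
            raise ValueError("transfer amounts must be nonnegative")
    total = arr.sum(axis=1)
    out = np.where(np.isnan(total), np.nan, (total > 0).astype(float))
    return (
        float(out[0]) if out.shape[0] == 1 and np.ndim(transfers_give) <= 1 else out
    )


def friend_frequency(contact_freq):
    """Validated pass-through of the 0-6 social-contact frequency scale."""
    arr = np.asarray(contact_freq)
    vals = arr[~pd.isna(arr)].astype(float)
    if vals.size and (np.any(vals < 0) or np.any(vals > 6) or np.any(vals % 1 != 0)):
        raise ValueError("contact frequency must be an integer in [0, 6]")
    if np.ndim(contact_freq) == 0:
        return int(contact_freq)
    return arr


def kmo(indicator_matrix) -> PCADiagnostics:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Overall KMO is ``sum r_ij^2 / (sum r_ij^2 + sum p_ij^2)`` over i != j,
    where ``r`` are Pearson correlations and ``p`` the partial correlations
    obtained from the inverse correlation matrix
    (``p_ij = -c_ij / sqrt(c_ii c_jj)``).  Per-item MSA restricts both sums
    to row i.  An exactly uncorrelated design (0/0) is reported as KMO 0
    with a warning.  Only the KMO fields of the returned diagnostics are
    populated; eigen-structure fields are filled by :func:`friendship_index`.
    """
    X = _validated_indicator_matrix(indicator_matrix, min_cols=3)
    names = list(indicator_matrix.columns) if isinstance(indicator_matrix, pd.DataFrame) else [
        f"x{i+1}" for i in range(X.shape[1])
    ]
    Rm = np.corrcoef(X, rowvar=False)
    try:
        C = np.linalg.inv(Rm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; KMO partial correlations undefined"
        ) from exc
    dsq = np.sqrt(np.outer(np.diag(C), np.diag(C)))
    P = -C / dsq
    off = ~np.eye(Rm.shape[0], dtype=bool)
    r2 = Rm**2
    p2 = P**2
    num = r2[off].sum()
    den = num + p2[off].sum()
    # a design with (numerically) all-zero pairwise correlations leaves the
    # defining ratio 0/0; report 0 by convention
    if den == 0.0 or np.max(np.abs(Rm[off])) < 1e-12:
        warnings.warn(
            "all pairwise and partial correlations are zero; KMO reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        overall = 0.0
        per_item = np.zeros(Rm.shape[0])
    else:
        overall = num / den
        num_i = (r2 * off).sum(axis=1)
        den_i = num_i + (p2 * off).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_item = np.where(den_i > 0, num_i / den_i, 0.0)
    p = Rm.shape[0]
    return PCADiagnostics(
        kmo_overall=float(overall),
        kmo_per_item=per_item,
        eigenvalues=np.array([]),
        proportions=np.array([]),
        cumulative=np.array([]),
        loadings=np.empty((0, p)),
        n_retained=0,
        indicator_names=names,
    )


def _validated_indicator_matrix(indicator_matrix, min_cols: int) -> np.ndarray:
    if isinstance(indicator_matrix, pd.DataFrame):
        X = indicator_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(indicator_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < min_cols:
        raise ValueError(f"indicator matrix must be 2-D with >= {min_cols} columns")
    if np.isnan(X).any():
        raise ValueError("indicator matrix must be complete cases (no NaN)")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than indicators")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"constant indicator column(s) at position(s) {bad}")
    return X


def friendship_index(indicator_matrix) -> tuple[np.ndarray, PCADiagnostics]:
    """First-principal-component friendship index on standardized indicators.

    Columns are standardized to mean 0 / variance 1; the correlation matrix
    is eigendecomposed; components with eigenvalue >= 1 are retained (at
    least one); scores project the standardized data on the first retained
    component, sign-oriented so the first indicator (social spending) loads
    positively.  Scores have exact mean 0 by construction.
    """
    X = _validated_indicator_matrix(indicator_matrix, min_cols=3)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    diag = kmo(indicator_matrix)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Rm = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(Rm)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    p = len(evals)
    proportions = evals / evals.sum()
    cumulative = np.cumsum(proportions)
    n_retained = max(1, int(np.sum(evals >= 1.0)))
    v1 = evecs[:, 0].copy()
    # eigenvector sign is arbitrary: anchor on the first nonzero loading
    anchor = np.flatnonzero(np.abs(v1) > 1e-12)
    if anchor.size and v1[anchor[0]] < 0:
        v1 = -v1
        evecs[:, 0] = v1
    scores = Z @ v1
    scores = scores - scores.mean()  # exact centering against float drift
    diag.eigenvalues = evals
    diag.proportions = proportions
    diag.cumulative = cumulative
    diag.loadings = evecs.T
    diag.n_retained = n_retained
    return scores, diag


def build_index_bundle(df: pd.DataFrame) -> tuple[pd.DataFrame, PCADiagnostics]:
    """Derive all tie regressors for a respondent table.

    Adds ``hosnet_R``, ``clan`` (from the ten transfer columns), ``hosnet_F``
    (first-PC score over the complete-case friendship indicators; NaN for
    incomplete rows) and ``friend`` (validated contact frequency).  Returns
    the augmented copy and the PCA/KMO diagnostics.
    """
    out = df.copy()
    tr = out[TRANSFER_COLUMNS].astype(float)
    complete_tr = tr.notna().all(axis=1)
    hosnet_R = np.full(len(out), np.nan)
    clan = np.full(len(out), np.nan)
    if complete_tr.any():
        hosnet_R[complete_tr.to_numpy()] = kinship_index(tr.loc[complete_tr])
        clan[complete_tr.to_numpy()] = clan_indicator(tr.loc[complete_tr])
    out["hosnet_R"] = hosnet_R
    out["clan"] = clan

    ind = out[FRIENDSHIP_INDICATORS].astype(float)
    complete = ind.notna().all(axis=1)
    scores = np.full(len(out), np.nan)
    sub = ind.loc[complete]
    scores_sub, diag = friendship_index(sub)
    scores[complete.to_numpy()] = scores_sub
    out["hosnet_F"] = scores
    out["friend"] = friend_frequency(out["contact_freq"].to_numpy())
    return out, diag
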