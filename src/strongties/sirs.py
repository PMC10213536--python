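"""SIRS information-diffusion model of the formal-care market.

The long-term-care market is modelled as a closed population of size ``N``
split into three compartments: people who have not chosen formal care and
are unaware of their care risk (``S``), people who perceive the risk but
have not yet chosen formal care (``I``), and people who have chosen formal
care (``R``).  Risk information spreads through social contact at rate
``alpha`` (the strength of strong social ties), risk-aware individuals adopt
formal care through learning/imitation at rate ``beta``, revert to
unawareness without adopting at rate ``delta``, and adopters abandon formal
care and return to ``S`` at rate ``lam``:

    dS/dt = -alpha*S*I + lam*R + delta*I
    dI/dt =  alpha*S*I - beta*I - delta*I
    dR/dt =  beta*I - lam*R

The population is conserved (the right-hand sides sum to zero), and the
system has a closed-form interior equilibrium

    S* = (beta + delta) / alpha
    I* = lam * (N - S*) / (beta + lam)
    R* = beta * (N*alpha - beta - delta) / (alpha * (lam + beta))

which is feasible (``I* > 0``) exactly when ``alpha * N > beta + delta``;
otherwise the system settles at the adoption-free state ``(N, 0, 0)``.

Note: ``alpha`` and ``beta`` here are contagion rates, unrelated to the
regression coefficients in :mod:`strongties.glm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SIRSParams",
    "SIRSTrajectory",
    "EquilibriumResult",
    "derivatives",
    "steady_state",
    "simulate",
    "comparative_statics",
]


@dataclass(frozen=True)
class SIRSParams:
    """Rates of the SIRS care-market model; all strictly positive.

    alpha : social-contact / tie-strength rate (per person per unit time)
    beta  : adoption (learning/imitation) rate I -> R
    lam   : abandonment rate R -> S
    delta : non-adoption reversion rate I -> S
    N     : constant total population (default 1, i.e. proportions)
    """

    alpha: float
    beta: float
    lam: float
    delta: float
    N: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SIRS rate {name!r} must be > 0, got {v!r}")
        if not np.isfinite(self.N) or self.N <= 0:
            raise ValueError(f"population N must be > 0, got {self.N!r}")

    @property
    def endemic_threshold(self) -> float:
        """alpha*N - (beta + delta); positive iff the interior equilibrium exists."""
        return self.alpha * self.N - (self.beta + self.delta)


@dataclass(frozen=True)
class SIRSTrajectory:
    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "S": self.S, "I": self.I, "R": self.R})

    @property
    def terminal(self) -> tuple[float, float, float]:
        return float(self.S[-1]), float(self.I[-1]), float(self.R[-1])


@dataclass(frozen=True)
class EquilibriumResult:
    S_star: float
    I_star: float
    R_star: float
    endemic: bool

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.S_star, self.I_star, self.R_star)


def derivatives(state, params: SIRSParams) -> tuple[float, float, float]:
    """Right-hand sides (dS, dI, dR) of the care-market system.

    Incidence is bilinear ``alpha*S*I`` (with N = 1 this coincides with
    frequency-dependent mixing).  Raises ValueError on negative state.
    """
    S, I, R = (float(x) for x in state)
    if S < 0 or I < 0 or R < 0:
        raise ValueError(f"state components must be >= 0, got {(S, I, R)}")
    a, b, l, d = params.alpha, params.beta, params.lam, params.delta
    dS = -a * S * I + l * R + d * I
    dI = a * S * I - b * I - d * I
    dR = b * I - l * R
    return dS, dI, dR


def steady_state(params: SIRSParams) -> EquilibriumResult:
    """Closed-form equilibrium of the care market.

    Returns the interior (endemic) equilibrium when ``alpha*N > beta+delta``,
    otherwise the adoption-free state ``(N, 0, 0)``.
    """
    a, b, l, d, N = params.alpha, params.beta, params.lam, params.delta, params.N
    if params.endemic_threshold > 0:
        S = (b + d) / a
        I = l * (N - S) / (b + l)
        R = b * (N * a - b - d) / (a * (l + b))
        return EquilibriumResult(S, I, R, endemic=True)
    return EquilibriumResult(float(N), 0.0, 0.0, endemic=False)


def simulate(
    params: SIRSParams,
    init_state,
    t_end: float,
    dt: float = 0.01,
    record_every: int = 1,
) -> SIRSTrajectory:
    """Integrate the system with a classical fixed-step 4th-order Runge-Kutta.

    ``init_state`` must be component-wise nonnegative and sum to ``N`` within
    1e-9 (relative).  ``record_every`` thins the stored trajectory; the final
    state is always recorded.  RK4 preserves the linear invariant S+I+R = N
    up to floating-point roundoff, so conservation holds to ~1e-12*N.
    """
    S0, I0, R0 = (float(x) for x in init_state)
    if min(S0, I0, R0) < 0:
        raise ValueError(f"initial state must be nonnegative, got {(S0, I0, R0)}")
    tot = S0 + I0 + R0
    if abs(tot - params.N) > 1e-9 * max(1.0, params.N):
        raise ValueError(
            f"initial state sums to {tot!r}, expected N = {params.N!r} (tol 1e-9)"
        )
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")

    n_steps = int(round(t_end / dt))
    a, b, l, d = params.alpha, params.beta, params.lam, params.delta

    def f(S, I, R):
        dS = -a * S * I + l * R + d * I
        dI = a * S * I - b * I - d * I
        dR = b * I - l * R
        return dS, dI, dR

    ts = [0.0]
    Ss = [S0]
    Is = [I0]
    Rs = [R0]
    S, I, R = S0, I0, R0
    h = dt
    for k in range(1, n_steps + 1):
        k1 = f(S, I, R)
        k2 = f(S + 0.5 * h * k1[0], I + 0.5 * h * k1[1], R + 0.5 * h * k1[2])
        k3 = f(S + 0.5 * h * k2[0], I + 0.5 * h * k2[1], R + 0.5 * h * k2[2])
        k4 = f(S + h * k3[0], I + h * k3[1], R + h * k3[2])
        S += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        I += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        R += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if k % record_every == 0 or k == n_steps:
            ts.append(k * h)
            Ss.append(S)
            Is.append(I)
            Rs.append(R)
    return SIRSTrajectory(
        t=np.asarray(ts), S=np.asarray(Ss), I=np.asarray(Is), R=np.asarray(Rs)
    )


def comparative_statics(params: SIRSParams, alpha_grid) -> pd.DataFrame:
    """Equilibrium compartments as the tie-strength rate ``alpha`` varies.

    In the endemic region ``S* = (beta+delta)/alpha`` is strictly decreasing
    in alpha (and independent of lam), while I* and R* are nondecreasing:
    stronger social ties shrink the uninformed non-adopter pool.

    Returns a tidy table with columns alpha, S_star, I_star, R_star, endemic.
    """
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("alpha_grid must be a nonempty 1-D sequence")
    if np.any(grid <= 0):
        raise ValueError("alpha_grid values must be > 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("alpha_grid must be strictly increasing")
    rows = []
    for a in grid:
        eq = steady_state(
            SIRSParams(alpha=float(a), beta=params.beta, lam=params.lam,
                       delta=params.delta, N=params.N)
        )
        rows.append((a, eq.S_star, eq.I_star, eq.R_star, eq.endemic))
    return pd.DataFrame(rows, columns=["alpha", "S_star", "I_star", "R_star", "endemic"])
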