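"""Deterministic models of resistance evolution under an antibiotic dose gradient.

Two models are implemented.  The first is an exactly solvable pair of linear
ODEs for a drug-susceptible strain ``S`` mutating (rate ``mu``) into a
resistant strain ``R`` whose effective dose is reduced by a factor ``lam`` at
a fitness cost ``ell``::

    dS/dt = (g(A) - d) S - mu S
    dR/dt = (ell g(lam A) - d) R + mu S

with per-capita dose response ``g`` (``g(0) = 1``, strictly decreasing),
natural death rate ``d`` and dose ``A``.  Writing ``theta1 = g(A) - d - mu``
and ``theta2 = ell g(lam A) - d`` the solution from a clonal start
(``S(0)=1, R(0)=0``) is ``S(t) = exp(theta1 t)`` and
``R(t) = mu/(theta1-theta2) (exp(theta1 t) - exp(theta2 t))``.  The selection
coefficient ``s(A) = theta2 - theta1 = ell g(lam A) - g(A) + mu`` is
single-peaked in dose ("inverted-U"); its maximiser is the *hotspot* dose,
available in closed form for an exponential dose response.

The second model adds logistic competition at unit carrying capacity::

    dS/dt = S (1 - A - (S + R)) - mu S
    dR/dt = R (1 - (S + R)) + mu S

whose total-density dose responses are monotone for short treatments but
become non-monotone as resistant subpopulations are released from
competition at intermediate doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "GrowthResponse",
    "TheoryParams",
    "MswBoundaries",
    "HotspotResult",
    "thetas",
    "exact_solution",
    "resistant_frequency",
    "selection_coefficient",
    "hotspot_dose",
    "msw_boundaries",
    "simulate_competition",
    "dose_response_time_difference",
]

#: Relative threshold below which theta1 and theta2 are treated as equal and
#: the l'Hopital limit of the printed solution is used.
THETA_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class GrowthResponse:
    """Dose-dependent per-capita growth rate ``g(A)`` with ``g(0) = 1``.

    Two forms: ``exponential`` decline ``g(A) = exp(-p A)`` and a decreasing
    ``hill`` function ``g(A) = 1 / ((A / k_half)^n_hill + 1)``.
    """

    form: Literal["exponential", "hill"]
    p: float = 1.0
    k_half: float = 1.0
    n_hill: float = 7.0

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "hill"):
            raise ValueError(f"unknown growth-response form {self.form!r}")
        if self.form == "exponential" and not (np.isfinite(self.p) and self.p > 0):
            raise ValueError("exponential growth response requires p > 0")
        if self.form == "hill" and not (
            np.isfinite(self.k_half)
            and self.k_half > 0
            and np.isfinite(self.n_hill)
            and self.n_hill > 0
        ):
            raise ValueError("hill growth response requires k_half > 0 and n_hill > 0")

    def __call__(self, A):
        A = np.asarray(A, dtype=float)
        if self.form == "exponential":
            return np.exp(-self.p * A)
        return 1.0 / ((A / self.k_half) ** self.n_hill + 1.0)

    def derivative(self, A):
        """dg/dA, analytic."""
        A = np.asarray(A, dtype=float)
        if self.form == "exponential":
            return -self.p * np.exp(-self.p * A)
        x = (A / self.k_half) ** self.n_hill
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -self.n_hill * x / np.where(A > 0, A, np.nan) / (x + 1.0) ** 2
        return np.where(A > 0, out, 0.0 if self.n_hill > 1 else out)

    def inverse(self, y: float) -> float:
        """Dose at which g(A) = y, for y in (0, 1)."""
        if not 0.0 < y < 1.0:
            raise ValueError("g takes values in (0, 1) for A > 0")
        if self.form == "exponential":
            return math.log(1.0 / y) / self.p
        return self.k_half * (1.0 / y - 1.0) ** (1.0 / self.n_hill)


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the exactly solvable model.

    mu : mutation rate from S to R (per unit time)
    d : natural death rate (per unit time)
    ell : fitness-cost multiplier on R's growth, 0 < ell < 1 allowed up to 1
    lam : dose-scaling experienced by R, 0 < lam <= 1
    g : dose response shared by both strains
    """

    mu: float
    d: float
    ell: float
    lam: float
    g: GrowthResponse

    def __post_init__(self) -> None:
        for name in ("mu", "d", "ell", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {name}={v}")
        if self.mu < 0 or self.d < 0:
            raise ValueError("mu and d must be non-negative")
        if not (0.0 < self.ell <= 1.0 and 0.0 < self.lam <= 1.0):
            raise ValueError("require 0 < ell <= 1 and 0 < lam <= 1")


@dataclass(frozen=True)
class MswBoundaries:
    """Mutant-selection-window boundaries; ``None`` marks "not attained"."""

    msc: Optional[float]
    mic_s: Optional[float]
    mpc: Optional[float]


@dataclass(frozen=True)
class HotspotResult:
    dose: float
    method: Literal["closed_form", "numeric"]
    location: Literal["interior", "origin", "edge"]
    s_max: float


def thetas(params: TheoryParams, A: float) -> tuple[float, float]:
    """Net growth rates (theta1, theta2) of S and R at dose A."""
    g = params.g
    theta1 = float(g(A)) - params.d - params.mu
    theta2 = params.ell * float(g(params.lam * A)) - params.d
    return theta1, theta2


def _degenerate(theta1: float, theta2: float) -> bool:
    return abs(theta1 - theta2) < THETA_DEGENERACY_RTOL * max(1.0, abs(theta1))


def exact_solution(
    params: TheoryParams, A: float, times: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (S(t), R(t)) from the clonal initial condition S=1, R=0."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    theta1, theta2 = thetas(params, A)
    S = np.exp(theta1 * t)
    if _degenerate(theta1, theta2):
        R = params.mu * t * np.exp(theta1 * t)
    else:
        R = params.mu / (theta1 - theta2) * (np.exp(theta1 * t) - np.exp(theta2 * t))
    return S, R


def resistant_frequency(params: TheoryParams, A: float, t) -> np.ndarray:
    """Frequency rho(t) = S/(S+R) of the susceptible strain.

    Uses the printed closed form
    ``rho = 1 / (1 + mu (1 - exp((theta2-theta1) t)) / (theta1 - theta2))``
    which depends on d only through theta1 - theta2, i.e. not at all.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    theta1, theta2 = thetas(params, A)
    if _degenerate(theta1, theta2):
        return 1.0 / (1.0 + params.mu * t)
    dth = theta1 - theta2
    return 1.0 / (1.0 + params.mu * (1.0 - np.exp(-dth * t)) / dth)


def selection_coefficient(params: TheoryParams, A) -> np.ndarray:
    """s(A) = theta2 - theta1 = ell g(lam A) - g(A) + mu."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("dose must be non-negative")
    g = params.g
    return params.ell * g(params.lam * A) - g(A) + params.mu


def hotspot_dose(
    params: TheoryParams,
    method: Literal["auto", "closed_form", "numeric"] = "auto",
    A_max: Optional[float] = None,
    n_grid: int = 512,
) -> HotspotResult:
    """Dose maximising the selection coefficient s(A).

    For an exponential dose response the maximiser has the closed form
    ``A_hot = 1/(p (1 - lam)) ln(1/(ell lam))`` (positive whenever
    ``0 < ell, lam < 1``).  Otherwise (and for ``method='numeric'``) s(A) is
    maximised on a log-spaced grid over ``[1e-4, A_max]`` and refined by
    bounded scalar minimisation to relative tolerance 1e-8.  The maximum may
    sit at the origin or run off the bracket edge; the ``location`` field
    reports which.
    """
    if A_max is None:
        A_max = (
            100.0 / params.g.p
            if params.g.form == "exponential"
            else 100.0 * params.g.k_half
        )
    use_closed = params.g.form == "exponential" and method in ("auto", "closed_form")
    if method == "closed_form" and params.g.form != "exponential":
        raise ValueError("closed form only available for the exponential response")
    if use_closed:
        if params.ell * params.lam >= 1.0:
            # degenerate: no interior maximum of s
            a_hot, loc = 0.0, "origin"
        else:
            a_hot = (
                1.0
                / (params.g.p * (1.0 - params.lam))
                * math.log(1.0 / (params.ell * params.lam))
            )
            loc = "interior"
        return HotspotResult(a_hot, "closed_form", loc, float(selection_coefficient(params, a_hot)))

    grid = np.concatenate([[0.0], np.geomspace(1e-4, A_max, n_grid)])
    s_grid = selection_coefficient(params, grid)
    i = int(np.argmax(s_grid))
    if i == 0:
        return HotspotResult(0.0, "numeric", "origin", float(s_grid[0]))
    if i == len(grid) - 1:
        return HotspotResult(float(grid[-1]), "numeric", "edge", float(s_grid[-1]))
    lo, hi = grid[i - 1], grid[i + 1]
    res = minimize_scalar(
        lambda a: -float(selection_coefficient(params, a)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8 * max(1.0, hi)},
    )
    a_hot = float(res.x)
    return HotspotResult(a_hot, "numeric", "interior", float(selection_coefficient(params, a_hot)))


def msw_boundaries(params: TheoryParams, A_max: Optional[float] = None) -> MswBoundaries:
    """Mutant selection window: MSC, ancestral MIC and MPC.

    mic_s solves g(A) = d; mpc solves ell g(lam A) = d; msc is the smallest
    non-negative dose with s(A) = 0 (zero when s(0) > 0).  Each is ``None``
    when the defining equation has no root at the given parameters.
    """
    g = params.g
    mic_s = g.inverse(params.d) if 0.0 < params.d < 1.0 else None
    y = params.d / params.ell
    mpc = g.inverse(y) / params.lam if 0.0 < y < 1.0 else None

    s0 = float(selection_coefficient(params, 0.0))
    if s0 > 0:
        msc: Optional[float] = 0.0
    else:
        if A_max is None:
            A_max = 100.0 / g.p if g.form == "exponential" else 100.0 * g.k_half
        grid = np.linspace(0.0, A_max, 4096)
        s = np.asarray(selection_coefficient(params, grid))
        sign_change = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0]
        if len(sign_change) == 0:
            msc = None
        else:
            j = sign_change[0]
            msc = float(
                brentq(
                    lambda a: float(selection_coefficient(params, a)),
                    grid[j],
                    grid[j + 1],
                    xtol=1e-10,
                    rtol=1e-10,
                )
            )
    return MswBoundaries(msc=msc, mic_s=mic_s, mpc=mpc)


def simulate_competition(
    A: float,
    mu: float,
    S0: float,
    R0: float,
    t_end: float,
    dt_out: float,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate the logistic competition model; returns columns t, S, R.

    dS/dt = S (1 - A - (S+R)) - mu S ;  dR/dt = R (1 - (S+R)) + mu S.
    Negative round-off is clipped to zero in the output.
    """
    if S0 < 0 or R0 < 0:
        raise ValueError("initial densities must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    def rhs(t, y):
        S, R = y
        N = S + R
        return [S * (1.0 - A - N) - mu * S, R * (1.0 - N) + mu * S]

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(rhs, (0.0, t_end), [S0, R0], t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.4g}: {sol.message}")
    S = np.clip(sol.y[0], 0.0, None)
    R = np.clip(sol.y[1], 0.0, None)
    return pd.DataFrame({"t": sol.t, "S": S, "R": R})


def dose_response_time_difference(
    A_grid: Sequence[float],
    mu: float,
    S0: float,
    R0: float,
    t_snapshots: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dynamic dose responses of total density and their time differences.

    Returns (density, diffs, argmax): ``density`` has one row per
    (dose, snapshot) with the total density N = S + R; ``diffs`` holds the
    forward difference (N(A, t2) - N(A, t1)) / (t2 - t1) for consecutive
    snapshot pairs; ``argmax`` reports, per pair, the dose where that rate of
    density change is largest — the empirical analogue of the hotspot.
    """
    t_snapshots = np.asarray(sorted(t_snapshots), dtype=float)
    if len(t_snapshots) < 2:
        raise ValueError("need at least two snapshot times")
    rows = []
    for A in A_grid:

        def rhs(t, y):
            S, R = y
            N = S + R
            return [S * (1.0 - A - N) - mu * S, R * (1.0 - N) + mu * S]

        s = solve_ivp(
            rhs,
            (0.0, float(t_snapshots[-1])),
            [S0, R0],
            t_eval=t_snapshots,
            rtol=1e-8,
            atol=1e-9,
        )
        for t, S, R in zip(s.t, s.y[0], s.y[1]):
            rows.append({"dose": A, "t": t, "S": max(S, 0.0), "R": max(R, 0.0)})
    density = pd.DataFrame(rows)
    density["total"] = density["S"] + density["R"]

    diff_rows = []
    for t1, t2 in zip(t_snapshots[:-1], t_snapshots[1:]):
        n1 = density[density["t"] == t1].set_index("dose")["total"]
        n2 = density[density["t"] == t2].set_index("dose")["total"]
        for A in n1.index:
            diff_rows.append(
                {
                    "dose": A,
                    "t_start": t1,
                    "t_end": t2,
                    "delta_rate": (n2[A] - n1[A]) / (t2 - t1),
                }
            )
    diffs = pd.DataFrame(diff_rows)
    argmax = (
        diffs.loc[diffs.groupby(["t_start", "t_end"])["delta_rate"].idxmax()]
        .reset_index(drop=True)
        .rename(columns={"dose": "argmax_dose"})
    )
    return density, diffs, argmax
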