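"""Growth-curve model selection, Hill dose-response fits, MIC (IC99) and EAD.

Each well-season OD trace is fitted with three candidate growth laws

    linear       B(t) = B0 + r t
    exponential  B(t) = B0 + a exp(r t)
    logistic     B(t) = B0 + K / (1 + a exp(-r t))

where ``B0`` is an inferred blank.  The winner by corrected AIC supplies the
blank used downstream.  24-h densities across a dose gradient are summarised
by a decreasing Hill function ``B(A) = b_floor + (b_max - b_floor) /
(1 + (A/k_half)^n_hill)`` from which the MIC is read off as the IC99 (the
dose where density falls to 1% of the drug-free density) and the effective
antibiotic dose (EAD) of a treated culture is the ancestral-dose equivalent
of its density, ``B^{-1}(B*)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "DoseResponse",
    "HillFit",
    "HillFitError",
    "fit_growth_models",
    "blank_correct",
    "fit_hill",
    "mic_ic99",
    "ead",
]


class HillFitError(RuntimeError):
    """Raised when dose-response data violate the decreasing-Hill assumption."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well-season trace: OD600 (and optional GFP) at ~20-min spacing."""

    well_id: str
    season: int
    dose: float
    times: np.ndarray
    od: np.ndarray
    gfp: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if self.gfp is not None:
            object.__setattr__(self, "gfp", np.asarray(self.gfp, dtype=float))
        if len(t) != len(od):
            raise ValueError("times and od must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"times not strictly increasing in well {self.well_id}")
        if not np.all(np.isfinite(od)):
            raise ValueError(f"non-finite OD in well {self.well_id}")


@dataclass(frozen=True)
class GrowthFit:
    """Selected growth model for one curve.

    ``model`` is the AICc-minimal law; ``aicc_all`` keeps every candidate's
    score so the margin of selection is inspectable.
    """

    model: Literal["linear", "exponential", "logistic"]
    B0: float
    r: float
    a: Optional[float]
    K: Optional[float]
    rss: float
    aicc: float
    n_obs: int
    aicc_all: dict

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            return self.B0 + self.r * t
        if self.model == "exponential":
            return self.B0 + self.a * np.exp(self.r * t)
        return self.B0 + self.K / (1.0 + self.a * np.exp(-self.r * t))


@dataclass(frozen=True)
class DoseResponse:
    """Replicate x dose matrix of densities at a fixed time (usually 24 h)."""

    strain: str
    season: int
    doses: np.ndarray
    densities: np.ndarray  # shape (n_replicates, n_doses)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        m = np.atleast_2d(np.asarray(self.densities, dtype=float))
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "densities", m)
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.diff(d) > 0):
            raise ValueError("doses must be sorted strictly increasing")
        if m.shape[1] != len(d):
            raise ValueError("densities must have one column per dose")

    @property
    def means(self) -> np.ndarray:
        return self.densities.mean(axis=0)


@dataclass(frozen=True)
class HillFit:
    b_max: float
    k_half: float
    n_hill: float
    b_floor: float
    param_cov: Optional[np.ndarray]
    mic: float
    mic_ci: tuple[float, float]
    k_half_ci: tuple[float, float] = (float("nan"), float("nan"))

    def predict(self, A) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        with np.errstate(over="ignore"):
            return self.b_floor + (self.b_max - self.b_floor) / (
                1.0 + (A / self.k_half) ** self.n_hill
            )

    def inverse(self, B: float) -> float:
        """Dose at which the fitted curve equals density B (b_floor < B <= b_max)."""
        if not self.b_floor < B <= self.b_max:
            raise ValueError("density outside the fitted range")
        if B == self.b_max:
            return 0.0
        ratio = (self.b_max - self.b_floor) / (B - self.b_floor) - 1.0
        return self.k_half * ratio ** (1.0 / self.n_hill)


# ---------------------------------------------------------------------------
# growth-model fitting


def _aicc(rss: float, n: int, k_model: int) -> float:
    # Gaussian least-squares AICc; k counts model parameters plus one
    # residual-variance parameter.
    k = k_model + 1
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_linear(t, y):
    coef, res, *_ = np.polyfit(t, y, 1, full=True)
    pred = np.polyval(coef, t)
    rss = float(np.sum((y - pred) ** 2))
    return {"B0": float(coef[1]), "r": float(coef[0]), "a": None, "K": None, "rss": rss}


def _profiled_linear(t, y, phi, positive_slope=True):
    """Least-squares (B0, c) in y ~ B0 + c * phi, with c >= 0 enforced."""
    X = np.column_stack([np.ones_like(t), phi])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    B0, c = float(coef[0]), float(coef[1])
    if positive_slope and c < 1e-12:
        c = 1e-12
        B0 = float(np.mean(y - c * phi))
    return B0, c


def _fit_exponential(t, y):
    # variable projection: for fixed r the model B0 + a exp(r t) is linear
    # in (B0, a), so only the rate is optimized nonlinearly
    r_max = min(50.0, 300.0 / max(float(t[-1]), 1e-9))

    def resid(p):
        phi = np.exp(p[0] * t)
        B0, a = _profiled_linear(t, y, phi)
        return B0 + a * phi - y

    span = max(y.max() - y.min(), 1e-6)
    r0 = max((np.log(span) - np.log(max(span / 10, 1e-6))) / max(t[-1] - t[0], 1e-9), 0.05)
    best = None
    for start in (r0, 0.5 * r0, 2.0 * r0):
        sol = least_squares(
            resid,
            [min(start, 0.9 * r_max)],
            bounds=([1e-6], [r_max]),
            ftol=1e-14,
            xtol=1e-14,
            max_nfev=400,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (float(sol.x[0]), rss)
    r, rss = best
    phi = np.exp(r * t)
    B0, a = _profiled_linear(t, y, phi)
    return {"B0": B0, "a": a, "r": r, "K": None, "rss": rss}


def _fit_logistic(t, y):
    # variable projection over (log a, r); (B0, K) solved linearly
    def resid(p):
        a, r = math.exp(p[0]), p[1]
        phi = 1.0 / (1.0 + a * np.exp(-r * t))
        B0, K = _profiled_linear(t, y, phi)
        return B0 + K * phi - y

    span = max(y.max() - y.min(), 1e-6)
    # linearized start: logit of the normalized trace is c + r t
    z = np.clip((y - y.min()) / span, 1e-2, 1.0 - 1e-2)
    slope, intercept = np.polyfit(t, np.log(z / (1.0 - z)), 1)
    r0 = float(np.clip(slope, 1e-3, 40.0))
    u0 = float(np.clip(-intercept, -20.0, 200.0))
    best = None
    for du in (0.0, -1.5, 1.5):
        sol = least_squares(
            resid,
            [u0 + du, r0],
            bounds=([-25.0, 1e-6], [230.0, 50.0]),
            ftol=1e-14,
            xtol=1e-14,
            max_nfev=400,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    (u, r), rss = best
    a = math.exp(float(u))
    phi = 1.0 / (1.0 + a * np.exp(-r * t))
    B0, K = _profiled_linear(t, y, phi)
    return {"B0": B0, "K": K, "a": a, "r": float(r), "rss": rss}


_MODEL_NPARAMS = {"linear": 2, "exponential": 3, "logistic": 4}
_FITTERS = {"linear": _fit_linear, "exponential": _fit_exponential, "logistic": _fit_logistic}


def fit_growth_models(curve: GrowthCurve) -> GrowthFit:
    """Fit all three growth laws and return the AICc-minimal one.

    Ties (within 1e-9) are broken toward the model with fewer parameters.
    A candidate that fails to converge is dropped with no further ado; if all
    fail a RuntimeError is raised.
    """
    t, y = curve.times, curve.od
    n = len(t)
    if n < 6:
        raise ValueError("need at least 6 observations to rank models by AICc")
    results = {}
    for name in ("linear", "exponential", "logistic"):
        try:
            # degenerate traces make the nonlinear fits overflow internally;
            # those candidates lose on AICc anyway, so keep the noise down
            with np.errstate(all="ignore"):
                res = _FITTERS[name](t, y)
        except Exception:
            continue
        res["aicc"] = _aicc(res["rss"], n, _MODEL_NPARAMS[name])
        if np.isfinite(res["aicc"]):
            results[name] = res
    if not results:
        raise RuntimeError(f"no growth model converged for well {curve.well_id}")
    # a residual SD below 1e-6 of the data scale is numerically an exact fit;
    # comparing AICc between two exact fits compares floating-point noise, so
    # exact fits are ranked by parsimony instead
    scale = max(float(np.max(np.abs(y))), 1e-6)
    exact = {name for name, r in results.items() if r["rss"] < n * (1e-6 * scale) ** 2}
    if exact:
        best = min(exact, key=lambda name: (_MODEL_NPARAMS[name], results[name]["aicc"]))
    else:
        best = min(
            results,
            key=lambda name: (round(results[name]["aicc"] / 1e-9), _MODEL_NPARAMS[name]),
        )
    res = results[best]
    return GrowthFit(
        model=best,
        B0=res["B0"],
        r=res["r"],
        a=res["a"],
        K=res["K"],
        rss=res["rss"],
        aicc=res["aicc"],
        n_obs=n,
        aicc_all={k: v["aicc"] for k, v in results.items()},
    )


def blank_correct(
    curve: GrowthCurve, fit: GrowthFit, gfp_blank: Optional[float] = None
) -> GrowthCurve:
    """Subtract the fitted blank B0 from the OD trace (and optionally GFP).

    Negative corrected values are kept: clipping would bias downstream noise
    statistics.
    """
    gfp = curve.gfp
    if gfp is not None and gfp_blank is not None:
        gfp = gfp - gfp_blank
    return replace(curve, od=curve.od - fit.B0, gfp=gfp)


# ---------------------------------------------------------------------------
# Hill dose-response fitting


def _hill(A, b_max, k_half, n_hill, b_floor):
    return b_floor + (b_max - b_floor) / (1.0 + (A / k_half) ** n_hill)


def _fit_hill_means(doses, means, fit_floor, rng=None):
    b_max0 = float(means.max())
    half = means.min() + (means.max() - means.min()) / 2.0
    k0 = float(doses[int(np.argmin(np.abs(means - half)))])
    k0 = max(k0, doses[doses > 0].min() if np.any(doses > 0) else 1.0)
    starts = [(b_max0, k0, 2.0)]
    if rng is not None:
        for _ in range(3):
            starts.append(
                (
                    b_max0 * rng.uniform(0.8, 1.2),
                    k0 * rng.uniform(0.5, 2.0),
                    rng.uniform(1.0, 6.0),
                )
            )
    last_err: Exception | None = None
    for b0, k0_, n0 in starts:
        try:
            if fit_floor:
                popt, pcov = curve_fit(
                    _hill,
                    doses,
                    means,
                    p0=[b0, k0_, n0, 0.0],
                    bounds=([1e-12, 1e-9, 1e-9, 0.0], [np.inf] * 4),
                    maxfev=20000,
                )
            else:
                popt, pcov = curve_fit(
                    lambda A, b, k, n: _hill(A, b, k, n, 0.0),
                    doses,
                    means,
                    p0=[b0, k0_, n0],
                    bounds=([1e-12, 1e-9, 1e-9], [np.inf] * 3),
                    maxfev=20000,
                )
                popt = np.append(popt, 0.0)
            return popt, pcov
        except Exception as err:  # try next start
            last_err = err
    raise HillFitError(f"Hill fit failed to converge: {last_err}")


def fit_hill(
    dr: DoseResponse,
    fit_floor: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: Literal["bootstrap", "covariance"] = "bootstrap",
) -> HillFit:
    """Fit a decreasing Hill function to replicate-mean densities.

    The MIC (IC99) and its 95% CI come, by default, from a nonparametric
    bootstrap over replicate rows; ``ci_method='covariance'`` instead
    propagates the fit covariance through the analytic IC99 by the delta
    method on parameter draws.
    """
    doses = dr.doses
    if len(doses) < 3:
        raise ValueError("need at least 3 doses for a Hill fit")
    means = dr.means
    if means[-1] > means[0]:
        raise HillFitError("densities increase with dose; decreasing Hill assumed")
    if np.ptp(means) < 1e-12 * max(1.0, abs(means[0])):
        raise HillFitError("no dose signal: densities constant across doses")
    rng = np.random.default_rng(seed)
    popt, pcov = _fit_hill_means(doses, means, fit_floor, rng)
    b_max, k_half, n_hill, b_floor = (float(v) for v in popt)

    fit0 = HillFit(b_max, k_half, n_hill, b_floor, pcov, math.nan, (math.nan, math.nan))
    mic = mic_ic99(fit0, zero_dose_density=b_max)

    mics = []
    k_halves = []
    n_rep = dr.densities.shape[0]
    if ci_method == "bootstrap" and n_rep > 1:
        for _ in range(n_boot):
            idx = rng.integers(0, n_rep, size=n_rep)
            bm = dr.densities[idx].mean(axis=0)
            if bm[-1] > bm[0]:
                continue
            try:
                p, _ = _fit_hill_means(doses, bm, fit_floor)
            except HillFitError:
                continue
            f = HillFit(*(float(v) for v in p), None, math.nan, (math.nan, math.nan))
            m = mic_ic99(f, zero_dose_density=float(p[0]))
            if np.isfinite(m):
                mics.append(m)
            k_halves.append(float(p[1]))
    elif ci_method == "covariance":
        try:
            draws = rng.multivariate_normal(popt[: pcov.shape[0]], pcov, size=n_boot)
            for p in draws:
                if np.any(p[:3] <= 0):
                    continue
                p4 = np.append(p, 0.0) if len(p) == 3 else p
                f = HillFit(*(float(v) for v in p4[:4]), None, math.nan, (math.nan, math.nan))
                m = mic_ic99(f, zero_dose_density=float(p4[0]))
                if np.isfinite(m):
                    mics.append(m)
        except np.linalg.LinAlgError:
            pass
    if mics:
        lo, hi = np.percentile(mics, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (math.nan, math.nan)
    if k_halves:
        lo, hi = np.percentile(k_halves, [2.5, 97.5])
        k_ci = (float(lo), float(hi))
    else:
        k_ci = (math.nan, math.nan)
    return HillFit(b_max, k_half, n_hill, b_floor, pcov, mic, ci, k_ci)


def mic_ic99(fit: HillFit, zero_dose_density: float) -> float:
    """IC99: the dose at which the fitted curve equals 1% of the drug-free density.

    Returns NaN ("not attained") when the Hill floor sits above that 1% level.
    """
    if zero_dose_density <= 0:
        raise ValueError("zero-dose density must be positive")
    target = zero_dose_density / 100.0
    if fit.b_floor >= target:
        return math.nan
    return fit.inverse(target)


def ead(ancestral: HillFit, b_star: float) -> float:
    """Effective antibiotic dose: ancestral-dose equivalent of density b_star.

    A treated culture reaching the untreated ancestral density has EAD 0; the
    larger b_star, the smaller the EAD.  Densities at or below the Hill floor
    are beyond the fitted range (NaN).
    """
    if not np.isfinite(b_star):
        raise ValueError("b_star must be finite")
    b0 = float(ancestral.predict(0.0))
    if b_star >= b0:
        return 0.0
    if b_star <= ancestral.b_floor:
        return math.nan
    return ancestral.inverse(b_star)
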