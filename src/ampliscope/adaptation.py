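"""Phenotypic rate-of-adaptation statistics and their dose-dependence.

The primary statistic is alpha = (delta_r / 2) / t_a: half the total change
of a phenotype series r(t) over a treatment, divided by the adaptive time
t_a at which the series first crosses the halfway level r(0) + delta_r/2.
Two per-capita growth-rate alternatives guard against the choice of growth
law: r_e, the maximal forward-difference per-capita rate evaluated on the
best-AICc model fit, and r_auc, end density over the area under the curve.

A dose profile of replicate ROA values is classified by its number of
interior local maxima: exactly one is an "inverted-U" whose argmax is the
hotspot dose; none distinguishes monotone ("L"-like) and flat profiles; more
than one is complex ("M").  A discrete-Fourier periodogram quantifies
non-biological oscillations that plate readers imprint on fluorescence
traces (dominant wavelengths near 10 h and 0.75 h in the emulated data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import ttest_1samp, ttest_ind

from .growth_dose import GrowthCurve, GrowthFit, fit_growth_models

__all__ = [
    "PhenotypeSeries",
    "RoaResult",
    "InvertedUSummary",
    "roa_alpha",
    "roa_growth_rate",
    "roa_auc",
    "dose_increment_change",
    "inverted_u_summary",
    "oscillation_periodogram",
]


@dataclass(frozen=True)
class PhenotypeSeries:
    """A longitudinal phenotype (OD or GFP-per-OD) for one replicate at one dose."""

    label: Literal["od", "gfp_per_od"]
    dose: float
    replicate: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class RoaResult:
    dose: float
    replicate: int
    metric: Literal["alpha", "r_e", "r_auc"]
    value: float
    t_a: Optional[float] = None
    delta_r: Optional[float] = None


def roa_alpha(
    series: PhenotypeSeries,
    endpoint_window: int = 3,
    rel_tol: float = 1e-9,
) -> RoaResult:
    """Rate of adaptation alpha = (delta_r/2) / t_a.

    r(0) and r(T) are short-window means (default: first/last 3 samples) to
    damp endpoint noise; t_a is the first linearly interpolated crossing of
    the level r(0) + delta_r/2.  A declining series yields negative alpha
    (loss of the phenotype); a constant series yields alpha = 0 with t_a
    undefined.
    """
    t, r = series.times, series.values
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    w = min(endpoint_window, len(t) // 2)
    r0 = float(np.mean(r[:w]))
    rT = float(np.mean(r[-w:]))
    delta = rT - r0
    scale = max(abs(r0), abs(rT), 1e-300)
    if abs(delta) < rel_tol * max(1.0, scale):
        return RoaResult(series.dose, series.replicate, "alpha", 0.0, None, 0.0)
    level = r0 + delta / 2.0
    # first crossing in the direction of the net change
    sgn = 1.0 if delta > 0 else -1.0
    above = sgn * (r - level) >= 0.0
    idx = np.nonzero(above)[0]
    if len(idx) == 0:
        raise RuntimeError(
            f"series never reaches its halfway level {level:.4g} "
            f"(r0={r0:.4g}, rT={rT:.4g}): non-monotone pathology"
        )
    i = int(idx[0])
    if i == 0:
        t_a = float(t[0]) if t[0] > 0 else float(t[1]) * 0.5
    else:
        f = (level - r[i - 1]) / (r[i] - r[i - 1])
        t_a = float(t[i - 1] + f * (t[i] - t[i - 1]))
    alpha = (delta / 2.0) / t_a
    return RoaResult(series.dose, series.replicate, "alpha", alpha, t_a, delta)


def roa_growth_rate(fit: GrowthFit, dt: float = 1.0 / 3.0, window: float = 24.0) -> float:
    """r_e: max over a 24-h window of the forward-difference per-capita rate.

    Evaluated on the fitted growth model B(t) (including its blank), with
    dt defaulting to the 20-min read interval:
    r_e = max_t  (B(t + dt) - B(t)) / (B(t) dt).
    """
    t = np.arange(0.0, window + 1e-9, dt)
    B = fit.predict(t)
    B_next = fit.predict(t + dt)
    if np.any(B <= 0):
        raise ValueError("fitted density non-positive on the window; per-capita rate undefined")
    return float(np.max((B_next - B) / (B * dt)))


def roa_auc(curve: GrowthCurve, window: float = 24.0) -> float:
    """r_auc = B(24 h) / integral_0^24 B(t) dt (trapezoidal), units 1/h."""
    mask = curve.times <= window + 1e-9
    t, B = curve.times[mask], curve.od[mask]
    if len(t) < 2 or t[-1] < window - 1e-6:
        raise ValueError("curve does not span the 24-h window")
    integral = float(np.trapezoid(B, t))
    if integral <= 0:
        raise ValueError("non-positive area under the curve")
    return float(B[-1]) / integral


def dose_increment_change(*dose_responses, labels: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-replicate density changes between adjacent doses, with t-tests.

    For each DoseResponse (e.g. the 24-h and 120-h snapshots) and each
    adjacent dose pair, computes the per-replicate difference in density, a
    two-sided one-sample t-test against zero change, and the direction.  No
    multiplicity correction is applied (raw P < 0.05 convention); apply one
    downstream if desired.
    """
    rows = []
    for which, dr in enumerate(dose_responses):
        label = labels[which] if labels is not None else which
        for j in range(len(dr.doses) - 1):
            diff = dr.densities[:, j + 1] - dr.densities[:, j]
            mean = float(np.mean(diff))
            se = float(np.std(diff, ddof=1) / math.sqrt(len(diff))) if len(diff) > 1 else math.nan
            if len(diff) > 1 and np.std(diff, ddof=1) > 0:
                p = float(ttest_1samp(diff, 0.0).pvalue)
            else:
                p = math.nan  # zero variance: test undefined
            rows.append(
                {
                    "snapshot": label,
                    "dose_lo": float(dr.doses[j]),
                    "dose_hi": float(dr.doses[j + 1]),
                    "mean_delta": mean,
                    "se": se,
                    "p_value": p,
                    "direction": "up" if mean > 0 else ("down" if mean < 0 else "none"),
                    "significant": bool(p < 0.05) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InvertedUSummary:
    argmax_dose: float
    classification: Literal["inverted_u", "monotone_down", "monotone_up", "flat", "complex"]
    dose_means: pd.DataFrame  # dose, mean, se, p_vs_zero_dose


def _as_roa_frame(roas) -> pd.DataFrame:
    if isinstance(roas, pd.DataFrame):
        return roas
    return pd.DataFrame(
        [{"dose": r.dose, "replicate": r.replicate, "value": r.value} for r in roas]
    )


def inverted_u_summary(
    roas,
    prominence_factor: float = 1.0,
    flat_rel_tol: float = 1e-9,
) -> InvertedUSummary:
    """Classify the dose profile of ROA values and locate its hotspot.

    Replicate means per dose are scanned for interior local maxima with a
    prominence floor of ``prominence_factor`` times the median replicate SE
    (zero when replicates are absent), so measurement noise does not mint
    spurious peaks.  One interior maximum is an inverted-U; none is monotone
    or flat; two or more is complex ("M"-shaped).  Per-dose significance
    against the zero-dose (lowest-dose) ROA uses a two-sample t-test.
    """
    df = _as_roa_frame(roas)
    doses = np.sort(df["dose"].unique())
    if len(doses) < 4:
        raise ValueError("need at least 4 doses to classify a dose profile")
    groups = {d: df.loc[df["dose"] == d, "value"].to_numpy() for d in doses}
    means = np.array([np.mean(groups[d]) for d in doses])
    ses = np.array(
        [
            np.std(groups[d], ddof=1) / math.sqrt(len(groups[d])) if len(groups[d]) > 1 else 0.0
            for d in doses
        ]
    )
    base = groups[doses[0]]
    pvals = []
    for d in doses:
        g = groups[d]
        if d == doses[0] or len(g) < 2 or len(base) < 2 or (np.std(g) == 0 and np.std(base) == 0):
            pvals.append(math.nan)
        else:
            pvals.append(float(ttest_ind(g, base).pvalue))
    dose_means = pd.DataFrame(
        {"dose": doses, "mean": means, "se": ses, "p_vs_zero_dose": pvals}
    )

    span = float(np.ptp(means))
    scale = max(np.max(np.abs(means)), 1e-300)
    if span < flat_rel_tol * max(1.0, scale):
        return InvertedUSummary(float(doses[int(np.argmax(means))]), "flat", dose_means)

    prom = prominence_factor * float(np.median(ses))
    peaks, _ = find_peaks(means, prominence=max(prom, 1e-12))
    n_peaks = len(peaks)
    argmax_dose = float(doses[int(np.argmax(means))])
    if n_peaks == 1:
        classification = "inverted_u"
        argmax_dose = float(doses[int(peaks[0])])
    elif n_peaks == 0:
        tol = max(prom, flat_rel_tol * scale)
        diffs = np.diff(means)
        if np.all(diffs <= tol):
            classification = "monotone_down"
        elif np.all(diffs >= -tol):
            classification = "monotone_up"
        else:
            classification = "complex"
    else:
        classification = "complex"
    return InvertedUSummary(argmax_dose, classification, dose_means)


def oscillation_periodogram(
    series: PhenotypeSeries,
    detrend: Literal["model", "mean", "none"] = "model",
    n_dominant: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Power spectrum of a phenotype trace and its dominant wavelengths.

    The trace is resampled to a uniform grid (linear interpolation), the
    trend removed (default: the best-AICc growth-model fit; ``mean``
    subtracts the mean only; ``none`` leaves the raw trace) and a real FFT
    power spectrum computed.  Returns (spectrum, dominant): ``spectrum`` has
    columns wavelength_h and power over interior frequencies, ``dominant``
    the wavelengths of the ``n_dominant`` highest power peaks.
    """
    t, v = series.times, series.values
    if len(t) < 16:
        raise ValueError("need at least 16 samples for a periodogram")
    dt = float(np.min(np.diff(t)))
    t_uniform = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    v_uniform = np.interp(t_uniform, t, v)

    if detrend == "model":
        curve = GrowthCurve("_spectrum", 0, series.dose, t_uniform, v_uniform)
        try:
            fit = fit_growth_models(curve)
            resid = v_uniform - fit.predict(t_uniform)
        except RuntimeError:
            resid = v_uniform - np.mean(v_uniform)
    elif detrend == "mean":
        resid = v_uniform - np.mean(v_uniform)
    else:
        resid = v_uniform

    power = np.abs(np.fft.rfft(resid)) ** 2
    freqs = np.fft.rfftfreq(len(resid), d=dt)
    # drop DC; interior frequencies only
    power, freqs = power[1:], freqs[1:]
    wavelengths = 1.0 / freqs
    spectrum = pd.DataFrame({"wavelength_h": wavelengths, "power": power})

    peaks, _ = find_peaks(power)
    if len(peaks) == 0:
        peaks = np.arange(len(power))
    order = peaks[np.argsort(power[peaks])[::-1]]
    floor = 1e-12 * max(float(np.max(power)), 1e-300)
    dominant = wavelengths[[i for i in order if power[i] > floor][:n_dominant]]
    return spectrum, dominant
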