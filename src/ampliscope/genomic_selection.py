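"""Selection proxies for gene amplifications and SNPs from sequencing data.

Copy-number change is read from depth-of-coverage: a feature's mean depth is
normalized to the genome-wide statistic (mean by default) and then to the
same ratio in the ancestral sample, giving "relative copies" (1 = ancestral,
>1 amplification, <1 deletion).  The time course of relative copies is
summarised by the saturating function

    F(t) = p1 (1 + t) / (1 + p2 (1 + t)),        p1, p2 >= 0, t in days

whose maximal derivative over the observed span, F'(t) = p1 / (1 + p2(1+t))^2,
is the *selection proxy* for the amplification.  Regressing the proxy on
dose with a quadratic locates the dose of maximal selection per gene.

SNP selection is proxied by the rate parameter s of a logistic frequency
trajectory f(t) = 1 / (1 + p exp(-s t)); trajectories never reaching 5%
frequency are filtered out.  Between-dose parallelism of a gene's SNP
frequencies is the Euclidean distance P(g) of its dose-frequency vector from
the nearest uniform vector lambda*(1,...,1), normalized by the maximal P
over the gene set; note that, as defined, a LARGE coefficient marks
across-dose variability rather than uniformity — the printed convention is
kept as is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar
from scipy import stats

__all__ = [
    "Feature",
    "CoverageTrack",
    "RelativeCopies",
    "AmplificationFit",
    "SnpTrajectory",
    "SnpSelectionFit",
    "ParallelismResult",
    "HotspotEstimate",
    "relative_copies",
    "fit_amplification",
    "gene_dose_hotspot",
    "fit_snp_selection",
    "filter_snp_trajectories",
    "parallelism",
]

#: Minimum (max-over-time) frequency for a SNP trajectory to be retained.
SNP_FREQUENCY_FILTER = 0.05


@dataclass(frozen=True)
class Feature:
    """A genomic interval, 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class CoverageTrack:
    """Windowed depth of coverage for one sample (bedGraph-like)."""

    sample_id: str
    dose: float
    time: float  # days since the first sequenced sample
    windows: pd.DataFrame  # columns chrom, start, end, depth

    def __post_init__(self) -> None:
        w = self.windows
        required = {"chrom", "start", "end", "depth"}
        if not required.issubset(w.columns):
            raise ValueError(f"coverage windows need columns {sorted(required)}")
        if (w["depth"] < 0).any():
            raise ValueError("negative depth")
        for chrom, grp in w.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping windows on {chrom}")

    def genome_stat(self, stat: Literal["mean", "median", "mode"] = "mean") -> float:
        d = self.windows["depth"].to_numpy(dtype=float)
        if stat == "mean":
            lengths = (self.windows["end"] - self.windows["start"]).to_numpy(dtype=float)
            out = float(np.average(d, weights=lengths))
        elif stat == "median":
            out = float(np.median(d))
        elif stat == "mode":
            out = float(stats.mode(np.round(d).astype(int), keepdims=False).mode)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        if out <= 0:
            raise ValueError("genome-wide depth statistic is non-positive")
        return out

    def feature_depth(self, feature: Feature) -> float:
        """Overlap-length-weighted mean depth over a feature interval."""
        w = self.windows[self.windows["chrom"] == feature.chrom]
        overlap = np.minimum(w["end"], feature.end) - np.maximum(w["start"], feature.start)
        mask = overlap > 0
        if not mask.any():
            raise ValueError(
                f"feature {feature.name} overlaps no coverage window in {self.sample_id}"
            )
        return float(np.average(w.loc[mask, "depth"], weights=overlap[mask]))


@dataclass(frozen=True)
class RelativeCopies:
    feature: Feature
    dose: float
    times: np.ndarray
    rel_copies: np.ndarray


@dataclass(frozen=True)
class AmplificationFit:
    p1: float
    p2: float
    s_proxy: float
    fit_rss: float
    converged: bool = True

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p1 * (1.0 + t) / (1.0 + self.p2 * (1.0 + t))

    def derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p1 / (1.0 + self.p2 * (1.0 + t)) ** 2


@dataclass(frozen=True)
class SnpTrajectory:
    position: int
    gene: str
    dose: float
    times: np.ndarray
    freq: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "freq", f)
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SnpSelectionFit:
    p: float
    s: float
    fit_rss: float
    converged: bool = True


@dataclass(frozen=True)
class ParallelismResult:
    gene: str
    f_vec: np.ndarray
    lambda_star: float
    P: float
    p_coeff: float
    parallel_flag: bool


@dataclass(frozen=True)
class HotspotEstimate:
    e_max: float
    s_max_pred: float
    keep_flag: bool
    coeffs: tuple[float, float, float]  # a, b, c of s(E) = a E^2 + b E + c
    resid_sd: float
    shape: Literal["peaked", "boundary", "flat"]


def relative_copies(
    tracks: Sequence[CoverageTrack],
    feature: Feature,
    ancestral: CoverageTrack,
    stat: Literal["mean", "median", "mode"] = "mean",
) -> RelativeCopies:
    """Copy number of a feature relative to genome depth and to the ancestor.

    Per sample: (feature mean depth / genome ``stat`` depth), divided by the
    identical ratio in the ancestral track.  Beware the whole-genome-mean
    bias: an amplified region inflates the genome mean, shrinking its own
    relative copies; the median statistic avoids this for small regions.
    """
    if not tracks:
        raise ValueError("no coverage tracks given")
    anc_ratio = ancestral.feature_depth(feature) / ancestral.genome_stat(stat)
    times, values = [], []
    for tr in sorted(tracks, key=lambda tr: tr.time):
        ratio = tr.feature_depth(feature) / tr.genome_stat(stat)
        times.append(tr.time)
        values.append(ratio / anc_ratio)
    doses = {tr.dose for tr in tracks}
    if len(doses) != 1:
        raise ValueError("all tracks must share one dose")
    return RelativeCopies(feature, doses.pop(), np.asarray(times), np.asarray(values))


def _amp_model(t, p1, p2):
    return p1 * (1.0 + t) / (1.0 + p2 * (1.0 + t))


_P_BOUND = 1e7  # upper bound keeps the flat-track limit p1 ~ p2 -> inf finite


def fit_amplification(rc: RelativeCopies) -> AmplificationFit:
    """Least-squares fit of F(t) = p1(1+t)/(1+p2(1+t)) with p1, p2 >= 0.

    The selection proxy is the maximal derivative of the fitted F over the
    observed span; for p2 > 0 the derivative p1/(1+p2(1+t))^2 decreases in t,
    so the maximum sits at the earliest observed time.
    """
    t, y = np.asarray(rc.times, dtype=float), np.asarray(rc.rel_copies, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points to fit the amplification model")
    y0 = max(float(y[0]), 1e-6)
    y_end = max(float(y[-1]), y0)
    # moment starts: asymptote p1/p2 ~ plateau; F(0) = p1/(1+p2)
    starts = []
    for plateau in (y_end, 2 * y_end, max(1.0, y_end)):
        for p2_0 in (0.5, 5.0, 50.0):
            starts.append((max(plateau * p2_0, 1e-3), p2_0))
    best = None
    for p1_0, p2_0 in starts:
        try:
            popt, _ = curve_fit(
                _amp_model,
                t,
                y,
                p0=[p1_0, p2_0],
                bounds=([0.0, 0.0], [_P_BOUND, _P_BOUND]),
                maxfev=20000,
            )
        except Exception:
            continue
        rss = float(np.sum((y - _amp_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return AmplificationFit(math.nan, math.nan, math.nan, math.nan, converged=False)
    (p1, p2), rss = best
    fit = AmplificationFit(float(p1), float(p2), 0.0, rss)
    s_proxy = float(np.max(fit.derivative(t)))
    return AmplificationFit(float(p1), float(p2), s_proxy, rss)


def gene_dose_hotspot(
    s_by_dose: Mapping[float, float],
    sd_screen: float = 3.0,
) -> HotspotEstimate:
    """Quadratic regression of the selection proxy on dose.

    Fits s(E) = a E^2 + b E + c by OLS; a concave fit (a < 0) yields an
    interior hotspot E_max = -b/(2a) clamped to the dose range, otherwise the
    predicted maximum sits on a boundary.  ``keep_flag`` marks genes whose
    predicted maximal s exceeds ``sd_screen`` times the regression residual
    SD — the screen used to declutter genome-wide hotspot maps.
    """
    items = sorted((float(e), float(s)) for e, s in s_by_dose.items())
    E = np.array([e for e, _ in items])
    s = np.array([v for _, v in items])
    if len(E) < 4:
        raise ValueError("need the selection proxy at >= 4 doses")
    if np.ptp(s) < 1e-12 * max(1.0, np.max(np.abs(s))):
        return HotspotEstimate(float(E[0]), float(s[0]), False, (0.0, 0.0, float(s[0])), 0.0, "flat")
    a, b, c = np.polyfit(E, s, 2)
    pred = np.polyval([a, b, c], E)
    dof = max(len(E) - 3, 1)
    resid_sd = float(np.sqrt(np.sum((s - pred) ** 2) / dof))
    if a < 0:
        e_max = float(np.clip(-b / (2 * a), E[0], E[-1]))
        shape = "peaked" if E[0] < e_max < E[-1] else "boundary"
    else:
        e_max = float(E[0] if np.polyval([a, b, c], E[0]) >= np.polyval([a, b, c], E[-1]) else E[-1])
        shape = "boundary"
    s_max = float(np.polyval([a, b, c], e_max))
    keep = bool(s_max > sd_screen * resid_sd) if resid_sd > 0 else bool(s_max > 0)
    return HotspotEstimate(e_max, s_max, keep, (float(a), float(b), float(c)), resid_sd, shape)


def _snp_model(t, p, s):
    return 1.0 / (1.0 + p * np.exp(-s * t))


def fit_snp_selection(traj: SnpTrajectory) -> SnpSelectionFit:
    """Fit the logistic f(t) = 1/(1 + p exp(-s t)) to a frequency trajectory.

    s (any sign) is the selection proxy; p > 0 encodes the initial odds
    against the variant, p = (1 - f0)/f0.  Starting values come from the
    observed initial frequency and the slope of the empirical log-odds.
    """
    t, f = traj.times, traj.freq
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.all(f == 0):
        return SnpSelectionFit(math.nan, math.nan, math.nan, converged=False)
    f0 = float(f[0])
    p0 = (1.0 - f0) / max(f0, 1e-3)
    fc = np.clip(f, 1e-4, 1 - 1e-4)
    logit = np.log(fc / (1 - fc))
    s0 = float(np.polyfit(t, logit, 1)[0]) if len(t) > 1 else 0.0
    best = None
    for start in ((p0, s0), (p0, 0.5), (max(p0, 1.0), 1.0)):
        try:
            popt, _ = curve_fit(
                _snp_model,
                t,
                f,
                p0=list(start),
                bounds=([1e-9, -np.inf], [np.inf, np.inf]),
                maxfev=20000,
            )
        except Exception:
            continue
        rss = float(np.sum((f - _snp_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return SnpSelectionFit(math.nan, math.nan, math.nan, converged=False)
    (p, s), rss = best
    return SnpSelectionFit(float(p), float(s), rss)


def filter_snp_trajectories(
    trajs: Sequence[SnpTrajectory], threshold: float = SNP_FREQUENCY_FILTER
) -> list[SnpTrajectory]:
    """Keep trajectories whose frequency reaches ``threshold`` at any time."""
    return [tr for tr in trajs if float(np.max(tr.freq)) >= threshold]


def _uniform_distance(f: np.ndarray) -> tuple[float, float]:
    """Closed-form projection onto the ray {lambda (1,..,1), lambda > 0}.

    The unconstrained minimiser is lambda = mean(f); the positivity
    constraint only binds when mean(f) <= 0, impossible for frequencies.
    """
    lam = max(float(np.mean(f)), 0.0)
    P = float(np.linalg.norm(f - lam))
    return lam, P


def parallelism(
    freqs_by_dose: Mapping[str, Sequence[float]],
    threshold: float = 0.7,
    freq_filter: float = SNP_FREQUENCY_FILTER,
    cross_check: bool = False,
) -> list[ParallelismResult]:
    """Parallelism coefficient p(g) = P(g) / P* across a dose gradient.

    P(g) = min_{lambda>0} ||f - lambda (1,...,1)||_2, with f the gene's SNP
    frequencies over the N doses; P* is the maximal P over genes with any
    frequency above ``freq_filter``.  Genes with p(g) > ``threshold`` are
    flagged.  As printed, the coefficient is largest for genes whose
    frequencies VARY most across doses (distance from uniformity); the
    convention is preserved rather than inverted.
    """
    genes = {
        g: np.asarray(f, dtype=float)
        for g, f in freqs_by_dose.items()
        if np.max(np.asarray(f, dtype=float)) > freq_filter
    }
    if not genes:
        return []
    lengths = {len(f) for f in genes.values()}
    if len(lengths) != 1:
        raise ValueError("all frequency vectors must have equal length")
    dist = {}
    for g, f in genes.items():
        lam, P = _uniform_distance(f)
        if cross_check:
            res = minimize_scalar(
                lambda l: float(np.linalg.norm(f - l)),
                bounds=(0.0, max(1.0, f.max()) * 2),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if abs(float(res.x) - lam) > 1e-8:
                raise AssertionError("closed-form lambda* disagrees with numeric minimiser")
        dist[g] = (lam, P)
    p_star = max(P for _, P in dist.values())
    out = []
    for g, f in genes.items():
        lam, P = dist[g]
        if p_star > 0:
            p_coeff = P / p_star
            flag = p_coeff > threshold
        else:
            p_coeff = math.nan  # all vectors uniform: coefficient undefined
            flag = False
        out.append(ParallelismResult(g, f, lam, P, p_coeff, flag))
    return out
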