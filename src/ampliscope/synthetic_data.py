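"""Synthetic study data with known ground truth.

Emulates the three data classes the analysis consumes:

* **Serial-transfer plate reads** — a 7-season, 8-replicate treatment across
  an erythromycin-like dose gradient (0..50 ug/ml).  Within a season,
  densities follow logistic competition between copy-number classes
  (1, 2, 3 copies of a resistance operon), each extra copy shielding the
  cell from a fraction of the dose; between seasons cultures are diluted
  1:100 into fresh drug.  Plate OD adds a well blank, multiplicative read
  noise and the two instrument oscillations (10 h and 0.75 h wavelengths)
  real plate readers imprint; GFP reports operon expression with
  per-extra-copy repression.
* **Coverage tracks** — negative-binomial per-window depths whose means
  scale with a feature's true copy number through time.
* **SNP trajectories** — logistic-selection frequency paths observed through
  binomial sampling at a stated read depth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .adaptation import PhenotypeSeries, roa_alpha
from .genomic_selection import CoverageTrack, Feature

__all__ = [
    "NoiseConfig",
    "GfpConfig",
    "SerialTransferConfig",
    "GroundTruth",
    "simulate_serial_transfer",
    "season_endpoint_series",
    "synth_coverage",
    "synth_snp_trajectories",
]


@dataclass(frozen=True)
class NoiseConfig:
    blank_mean: float = 0.07  # OD of sterile medium
    blank_sd: float = 0.005  # well-to-well blank variation
    mult_cv: float = 0.05  # multiplicative read noise, CV
    osc_amp: float = 0.005  # amplitude of each instrument oscillation (OD)
    osc_wavelengths_h: tuple[float, ...] = (10.0, 0.75)

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(blank_mean=0.0, blank_sd=0.0, mult_cv=0.0, osc_amp=0.0)


@dataclass(frozen=True)
class GfpConfig:
    per_copy: float = 1000.0  # fluorescence units per operon copy per unit density
    # expression multiplier per extra copy; sqrt(2/3) makes a tripled operon
    # express ~2x per cell (3 * repression^2 = 2), the calibration point for
    # amplified-operon repression
    repression: float = 0.8165


@dataclass(frozen=True)
class SerialTransferConfig:
    """Study design of the emulated treatment assay.

    Defaults mirror the experimental design: doses 0,5,...,50 ug/ml, seven
    24-h seasons, eight replicates, 20-min reads, 1:100 transfer.  The model
    dose unit is ``dose / mic_ug_ml``; ``copy_protection`` gives the
    fraction of that dose felt by cells with 1, 2, 3, ... operon copies, and
    ``mu_per_h`` the per-hour rate of gaining one copy.
    """

    doses: tuple[float, ...] = tuple(float(d) for d in range(0, 55, 5))
    n_seasons: int = 7
    n_reps: int = 8
    season_h: float = 24.0
    dt_h: float = 1.0 / 3.0
    dilution: float = 0.01
    mu_per_h: float = 2e-4
    mic_ug_ml: float = 32.0
    growth_rate_per_h: float = 0.7
    copy_protection: tuple[float, ...] = (1.0, 0.7, 0.49)
    inoculum: float = 0.01
    od_scale: float = 0.5  # OD600 per unit model density
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gfp: Optional[GfpConfig] = field(default_factory=GfpConfig)
    strain: str = "synthetic-AG100"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution <= 1.0:
            raise ValueError("dilution must lie in (0, 1]")
        if self.mu_per_h < 0 or self.growth_rate_per_h <= 0:
            raise ValueError("rates must be non-negative (growth positive)")
        n_steps = self.season_h / self.dt_h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt_h must divide season_h")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth recorded alongside a serial-transfer simulation."""

    doses: np.ndarray
    season_end_times_h: np.ndarray
    season_end_od: np.ndarray  # (n_doses, n_seasons), noiseless, blank-free
    resistant_fraction: np.ndarray  # (n_doses, n_seasons), copies >= 2
    alpha_by_dose: np.ndarray
    fastest_dose: float


def _season_rhs(cfg: SerialTransferConfig, A_model: float):
    lam = np.asarray(cfg.copy_protection, dtype=float)
    r, mu = cfg.growth_rate_per_h, cfg.mu_per_h
    n = len(lam)

    def rhs(t, y):
        total = float(np.sum(y))
        growth = r * y * (1.0 - lam * A_model - total)
        flux = np.zeros(n)
        flux[:-1] -= mu * y[:-1]  # gain-of-copy mutation chain
        flux[1:] += mu * y[:-1]
        return growth + flux

    return rhs


def _simulate_dose(cfg: SerialTransferConfig, dose: float):
    """Noise-free class densities on the 20-min grid for every season."""
    A_model = dose / cfg.mic_ug_ml
    rhs = _season_rhs(cfg, A_model)
    n_classes = len(cfg.copy_protection)
    t_season = np.arange(0.0, cfg.season_h + 0.5 * cfg.dt_h, cfg.dt_h)
    y = np.zeros(n_classes)
    y[0] = cfg.inoculum
    seasons = []
    for _ in range(cfg.n_seasons):
        sol = solve_ivp(rhs, (0.0, cfg.season_h), y, t_eval=t_season, rtol=1e-8, atol=1e-11)
        if not sol.success:
            raise RuntimeError(f"season integration failed at dose {dose}: {sol.message}")
        dens = np.clip(sol.y, 0.0, None)
        seasons.append(dens)
        y = dens[:, -1] * cfg.dilution
    return t_season, seasons


def _well_name(rep: int, dose_idx: int) -> str:
    return f"{chr(ord('A') + rep)}{dose_idx + 1}"


def season_endpoint_series(
    plate: pd.DataFrame,
    layout: pd.DataFrame,
    season_h: float = 24.0,
    label: str = "od",
) -> list[PhenotypeSeries]:
    """Per-well series of end-of-season densities across the whole treatment.

    The serial-transfer trace saw-tooths within each season; adaptation is
    read from the density reached at the end of each season, so the
    phenotype series handed to the ROA statistics has one value per season.
    """
    col = "od600" if label == "od" else "gfp_per_od"
    if label == "gfp_per_od":
        plate = plate.assign(gfp_per_od=plate["gfp"] / plate["od600"])
    out = []
    meta = layout.set_index("well")
    for well, grp in plate.groupby("well"):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy()
        v = grp[col].to_numpy()
        n_seasons = int(round(t[-1] / season_h))
        times, values = [], []
        for s in range(1, n_seasons + 1):
            # last reading before the transfer; the reading at exactly s*24 h
            # is the post-dilution start of the next season
            upper = s * season_h + (1e-9 if s == n_seasons else -1e-9)
            mask = t <= upper
            if not mask.any():
                continue
            times.append(s * season_h)
            values.append(v[mask][-1])
        out.append(
            PhenotypeSeries(
                label="od" if label == "od" else "gfp_per_od",
                dose=float(meta.loc[well, "dose_ug_ml"]),
                replicate=int(meta.loc[well, "replicate"]),
                times=np.asarray(times),
                values=np.asarray(values),
            )
        )
    return out


def simulate_serial_transfer(
    cfg: SerialTransferConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Run the serial-transfer assay; returns (plate table, layout, truth).

    Plate table is long-format (time_h, well, od600[, gfp]); layout maps
    wells to strain, dose and replicate.  Replicates share the deterministic
    within-season dynamics and differ in blank and read noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.copy_protection)
    plate_rows = []
    layout_rows = []
    n_doses = len(cfg.doses)
    season_end_od = np.zeros((n_doses, cfg.n_seasons))
    res_frac = np.zeros((n_doses, cfg.n_seasons))

    for di, dose in enumerate(cfg.doses):
        t_season, seasons = _simulate_dose(cfg, dose)
        # global 20-min grid: season s contributes [24s, 24(s+1)); the final
        # season keeps its right endpoint so the trace spans the full 168 h
        glob_t, glob_classes = [], []
        for s, dens in enumerate(seasons):
            keep = slice(None) if s == cfg.n_seasons - 1 else slice(0, len(t_season) - 1)
            glob_t.append(t_season[keep] + s * cfg.season_h)
            glob_classes.append(dens[:, keep])
            tot_end = float(dens[:, -1].sum())
            season_end_od[di, s] = cfg.od_scale * tot_end
            res_frac[di, s] = float(dens[1:, -1].sum()) / tot_end if tot_end > 0 else 0.0
        glob_t = np.concatenate(glob_t)
        classes = np.concatenate(glob_classes, axis=1)
        total = classes.sum(axis=0)
        signal = cfg.od_scale * total

        if cfg.gfp is not None:
            copies = np.arange(1, n_classes + 1)
            expr = cfg.gfp.per_copy * copies * cfg.gfp.repression ** (copies - 1)
            gfp_signal = cfg.od_scale * (expr[:, None] * classes).sum(axis=0)
        else:
            gfp_signal = None

        osc = cfg.noise.osc_amp * sum(
            np.sin(2.0 * np.pi * glob_t / wl) for wl in cfg.noise.osc_wavelengths_h
        )
        for rep in range(cfg.n_reps):
            well = _well_name(rep, di)
            layout_rows.append(
                {
                    "well": well,
                    "strain": cfg.strain,
                    "dose_ug_ml": dose,
                    "replicate": rep,
                }
            )
            blank = rng.normal(cfg.noise.blank_mean, cfg.noise.blank_sd)
            noise = rng.normal(0.0, cfg.noise.mult_cv, size=len(glob_t))
            od = blank + signal * (1.0 + noise) + osc
            row = {
                "time_h": glob_t,
                "well": np.repeat(well, len(glob_t)),
                "od600": od,
            }
            if gfp_signal is not None:
                gnoise = rng.normal(0.0, cfg.noise.mult_cv, size=len(glob_t))
                row["gfp"] = 20.0 * blank + gfp_signal * (1.0 + gnoise) + 100.0 * osc
            plate_rows.append(pd.DataFrame(row))

    plate = pd.concat(plate_rows, ignore_index=True)
    layout = pd.DataFrame(layout_rows)

    end_times = cfg.season_h * np.arange(1, cfg.n_seasons + 1)
    if cfg.n_seasons >= 3:
        alphas = np.array(
            [
                roa_alpha(
                    PhenotypeSeries("od", float(d), 0, end_times, season_end_od[i])
                ).value
                for i, d in enumerate(cfg.doses)
            ]
        )
    else:  # too few seasons for an adaptation rate
        alphas = np.full(n_doses, np.nan)
    truth = GroundTruth(
        doses=np.asarray(cfg.doses, dtype=float),
        season_end_times_h=end_times,
        season_end_od=season_end_od,
        resistant_fraction=res_frac,
        alpha_by_dose=alphas,
        fastest_dose=float(cfg.doses[int(np.argmax(alphas))]),
    )
    return plate, layout, truth


# ---------------------------------------------------------------------------
# coverage and SNP synthesis


def synth_coverage(
    genome_length: int,
    window: int,
    features: Sequence[Feature],
    copy_trajectories: Mapping[str, Mapping[float, Sequence[float]]],
    depth_mean: float = 200.0,
    dispersion: float = 20.0,
    times: Sequence[float] = (0.0, 2.0, 4.0),
    seed: int = 0,
) -> tuple[CoverageTrack, dict[tuple[float, float], CoverageTrack]]:
    """Negative-binomial coverage tracks with amplifying features.

    ``copy_trajectories[feature.name][dose]`` gives true copy numbers at
    each time in ``times``; per-window depth is NB-distributed with mean
    ``depth_mean * copies`` and shape ``dispersion``.  Returns the ancestral
    track (copies 1 everywhere) and a dict keyed by (dose, time).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    starts = np.arange(0, genome_length, window)
    ends = np.minimum(starts + window, genome_length)
    n_windows = len(starts)
    for i, f in enumerate(features):
        if f.end > genome_length:
            raise ValueError(f"feature {f.name} outside the genome")
        for other in features[i + 1 :]:
            if f.chrom == other.chrom and f.start < other.end and other.start < f.end:
                raise ValueError(f"overlapping features {f.name} and {other.name}")
    rng = np.random.default_rng(seed)

    def draw(mean_per_window: np.ndarray) -> np.ndarray:
        p = dispersion / (dispersion + mean_per_window)
        return rng.negative_binomial(dispersion, p).astype(float)

    def make_track(sample_id, dose, time, copies_of) -> CoverageTrack:
        mean = np.full(n_windows, depth_mean)
        for f in features:
            mask = (starts < f.end) & (ends > f.start)
            mean[mask] = depth_mean * copies_of(f)
        return CoverageTrack(
            sample_id,
            dose,
            time,
            pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": ends, "depth": draw(mean)}
            ),
        )

    ancestral = make_track("ancestral", 0.0, 0.0, lambda f: 1.0)
    tracks = {}
    doses = sorted({d for traj in copy_trajectories.values() for d in traj})
    for dose in doses:
        for ti, t in enumerate(times):
            def copies_of(f, _dose=dose, _ti=ti):
                traj = copy_trajectories.get(f.name, {})
                return float(traj[_dose][_ti]) if _dose in traj else 1.0

            tracks[(dose, float(t))] = make_track(
                f"d{dose:g}_t{t:g}", float(dose), float(t), copies_of
            )
    return ancestral, tracks


def synth_snp_trajectories(
    s_by_dose: Mapping[float, Sequence[float]],
    p0: float = 19.0,
    depth: int = 200,
    times: Sequence[float] = (0.0, 2.0, 4.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomially sampled logistic SNP trajectories.

    ``s_by_dose[dose]`` lists the true selection coefficient of each locus
    at that dose.  True frequencies follow f(t) = 1/(1 + p0 exp(-s t));
    observed frequencies are Binomial(depth, f)/depth.  Loci that never
    reach the 5% reporting threshold are still emitted — downstream
    filtering is the pipeline's job.  Returns (observations, truth).
    """
    if depth < 20:
        raise ValueError("read depth below the 20x calling threshold")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    obs_rows, truth_rows = [], []
    position = 1000
    for dose in sorted(s_by_dose):
        for locus, s in enumerate(s_by_dose[dose]):
            f_true = 1.0 / (1.0 + p0 * np.exp(-float(s) * t))
            reads = rng.binomial(depth, f_true)
            gene = f"locus{locus:04d}"
            truth_rows.append(
                {"position": position, "gene": gene, "dose": dose, "s_true": float(s), "p_true": p0}
            )
            for ti, time in enumerate(t):
                obs_rows.append(
                    {
                        "position": position,
                        "gene": gene,
                        "dose": dose,
                        "time_d": float(time),
                        "freq": reads[ti] / depth,
                        "depth": depth,
                    }
                )
            position += 997
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)
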