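"""Readers, writers, run configuration and end-to-end orchestration.

Canonical on-disk formats are plain text: long-format plate tables
(time_h, well, od600[, gfp]) with a layout table (well, strain, dose_ug_ml,
replicate); bedGraph coverage; BED features; TSV SNP tables (an optional
VCF ingester maps AF/AD fields to frequencies).  ``run_full_analysis``
strings the stages together in the order the analysis reads: dose-responses
and MIC -> ROA and EAD -> coverage-based amplification proxies -> per-gene
dose hotspots -> SNP selection and parallelism, emitting tidy TSVs and a
JSON summary, all randomness flowing from named seeds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import adaptation, genomic_selection, growth_dose, synthetic_data
from .genomic_selection import CoverageTrack, Feature, SnpTrajectory
from .growth_dose import DoseResponse, GrowthCurve

__all__ = [
    "RunConfig",
    "read_plate",
    "write_plate",
    "read_coverage",
    "read_features",
    "read_snps",
    "read_snps_vcf",
    "snp_table_to_trajectories",
    "curves_to_dose_response",
    "run_full_analysis",
]

log = logging.getLogger("ampliscope")

_PLATE_COLUMNS = {"time_h", "well", "od600"}
_LAYOUT_COLUMNS = {"well", "strain", "dose_ug_ml", "replicate"}


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: Path
    plate_path: Optional[Path] = None
    layout_path: Optional[Path] = None
    coverage_dir: Optional[Path] = None
    snp_path: Optional[Path] = None
    seed: int = 0
    season_h: float = 24.0
    bootstrap_n: int = 200
    norm_stat: str = "mean"
    sd_screen: float = 3.0
    simulate: bool = True  # fall back to the synthetic preset when no inputs given
    sim_config: Optional[synthetic_data.SerialTransferConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["out_dir"] = Path(raw["out_dir"])
        for key in ("plate_path", "layout_path", "coverage_dir", "snp_path"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# plate reader tables


def read_plate(path, layout_path, season_h: float = 24.0) -> list[GrowthCurve]:
    """Split a long-format plate table into per-well, per-season curves.

    Season boundaries fall every ``season_h`` hours; within a season, times
    are re-expressed relative to the season start.  Every well must appear
    in the layout.
    """
    plate = pd.read_csv(path, sep=None, engine="python")
    layout = pd.read_csv(layout_path, sep=None, engine="python")
    missing = _PLATE_COLUMNS - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    missing = _LAYOUT_COLUMNS - set(layout.columns)
    if missing:
        raise ValueError(f"layout table missing columns {sorted(missing)}")
    meta = layout.set_index("well")
    curves = []
    for well, grp in plate.groupby("well"):
        if well not in meta.index:
            raise ValueError(f"well {well!r} absent from the layout")
        dose = float(meta.loc[well, "dose_ug_ml"])
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(dtype=float)
        # a season covers [s*season_h, (s+1)*season_h): the read at exactly
        # s*season_h is the post-transfer start of season s+1.  The final
        # read of the assay keeps the last season's right endpoint.
        n_seasons = int(math.ceil(t[-1] / season_h - 1e-9))
        season_idx = np.minimum(np.floor(t / season_h + 1e-9).astype(int), n_seasons - 1)
        season_idx = np.maximum(season_idx, 0)
        for s in np.unique(season_idx):
            sel = season_idx == s
            gfp = grp["gfp"].to_numpy(dtype=float)[sel] if "gfp" in grp.columns else None
            curves.append(
                GrowthCurve(
                    well_id=well,
                    season=int(s) + 1,
                    dose=dose,
                    times=t[sel] - s * season_h,
                    od=grp["od600"].to_numpy(dtype=float)[sel],
                    gfp=gfp,
                )
            )
    return curves


def write_plate(plate: pd.DataFrame, layout: pd.DataFrame, plate_path, layout_path) -> None:
    plate.to_csv(plate_path, sep="\t", index=False)
    layout.to_csv(layout_path, sep="\t", index=False)


def curves_to_dose_response(
    curves: Sequence[GrowthCurve],
    layout: pd.DataFrame,
    season: int,
    at_h: float = 24.0,
    strain: str = "",
) -> DoseResponse:
    """Assemble the replicate x dose density matrix at a season's endpoint."""
    meta = layout.set_index("well")
    cells: dict[tuple[float, int], float] = {}
    for c in curves:
        if c.season != season:
            continue
        rep = int(meta.loc[c.well_id, "replicate"])
        idx = int(np.argmin(np.abs(c.times - at_h)))
        cells[(c.dose, rep)] = float(c.od[idx])
    doses = sorted({d for d, _ in cells})
    reps = sorted({r for _, r in cells})
    mat = np.array([[cells[(d, r)] for d in doses] for r in reps])
    return DoseResponse(strain=strain, season=season, doses=np.array(doses), densities=mat)


# ---------------------------------------------------------------------------
# genomic tables


def read_coverage(
    path, sample_id: str = "", dose: float = 0.0, time: float = 0.0, strict: bool = True
) -> CoverageTrack:
    """Read a bedGraph / 4-column TSV coverage track (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "depth"],
        header=None,
    )
    if strict and (df["start"] >= df["end"]).any():
        raise ValueError("invalid intervals: start must be < end (0-based half-open)")
    return CoverageTrack(sample_id or str(path), dose, time, df)


def read_features(path, strict: bool = True) -> list[Feature]:
    """Read a BED file of feature intervals."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    feats = []
    for _, row in df.iterrows():
        name = str(row[3]) if len(row) > 3 else f"{row[0]}:{row[1]}-{row[2]}"
        if strict and int(row[1]) >= int(row[2]):
            raise ValueError(f"invalid BED interval for {name}")
        feats.append(Feature(name, str(row[0]), int(row[1]), int(row[2])))
    return feats


def read_snps(path) -> pd.DataFrame:
    """Read a SNP frequency table (chrom?, position, gene, dose, time_d, freq, depth)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"position", "gene", "dose", "time_d", "freq", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    if ((df["freq"] < 0) | (df["freq"] > 1)).any():
        raise ValueError("SNP frequencies outside [0, 1]")
    return df


def read_snps_vcf(path, gene_field: str = "GENE") -> pd.DataFrame:
    """Extract allele frequencies from a VCF (AF info or AD of first sample)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            freq = None
            if "AF" in rec.info:
                af = rec.info["AF"]
                freq = float(af[0] if isinstance(af, tuple) else af)
            elif rec.samples and "AD" in rec.samples[0]:
                ad = rec.samples[0]["AD"]
                total = sum(ad)
                freq = ad[1] / total if total > 0 else math.nan
            if freq is None:
                continue
            rows.append(
                {
                    "chrom": rec.chrom,
                    "position": rec.pos,
                    "gene": rec.info.get(gene_field, "NA"),
                    "freq": freq,
                }
            )
    return pd.DataFrame(rows)


def snp_table_to_trajectories(df: pd.DataFrame) -> list[SnpTrajectory]:
    """Group a SNP table into per-locus, per-dose trajectories (unfiltered)."""
    out = []
    for (pos, gene, dose), grp in df.groupby(["position", "gene", "dose"]):
        grp = grp.sort_values("time_d")
        out.append(
            SnpTrajectory(
                position=int(pos),
                gene=str(gene),
                dose=float(dose),
                times=grp["time_d"].to_numpy(),
                freq=grp["freq"].to_numpy(),
                depth=grp["depth"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestration


def _phenotype_roa_table(plate, layout, season_h) -> pd.DataFrame:
    series = synthetic_data.season_endpoint_series(plate, layout, season_h=season_h)
    rows = []
    for s in series:
        res = adaptation.roa_alpha(s)
        rows.append(
            {
                "dose": s.dose,
                "replicate": s.replicate,
                "metric": "alpha",
                "value": res.value,
                "t_a": res.t_a,
                "delta_r": res.delta_r,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage on the configured (or synthetic) inputs.

    Returns the JSON-ready summary dict; tables land under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # --- phenotype inputs -------------------------------------------------
    if cfg.plate_path is not None:
        curves = read_plate(cfg.plate_path, cfg.layout_path, season_h=cfg.season_h)
        plate = pd.read_csv(cfg.plate_path, sep=None, engine="python")
        layout = pd.read_csv(cfg.layout_path, sep=None, engine="python")
        truth = None
    elif cfg.simulate:
        log.info("no plate input; simulating the synthetic treatment preset")
        sim_cfg = cfg.sim_config or synthetic_data.SerialTransferConfig(seed=cfg.seed)
        plate, layout, truth = synthetic_data.simulate_serial_transfer(sim_cfg)
        plate_path = out / "plate.tsv"
        write_plate(plate, layout, plate_path, out / "layout.tsv")
        curves = read_plate(plate_path, out / "layout.tsv", season_h=cfg.season_h)
        summary["ground_truth_fastest_dose"] = truth.fastest_dose
    else:
        raise ValueError("no plate input and simulation disabled")

    # --- growth fits and season dose-responses ----------------------------
    fits = {}
    for c in curves:
        try:
            fits[(c.well_id, c.season)] = growth_dose.fit_growth_models(c)
        except (RuntimeError, ValueError) as err:
            log.warning("growth fit failed for %s season %s: %s", c.well_id, c.season, err)
    fit_rows = [
        {"well": w, "season": s, "model": f.model, "B0": f.B0, "r": f.r, "aicc": f.aicc}
        for (w, s), f in fits.items()
    ]
    pd.DataFrame(fit_rows).to_csv(out / "growth_fits.tsv", sep="\t", index=False)

    # blank-correct every curve with its own fitted B0 before any density is
    # compared across doses; wells whose fit failed keep their raw trace
    corrected = [
        growth_dose.blank_correct(c, fits[(c.well_id, c.season)])
        if (c.well_id, c.season) in fits
        else c
        for c in curves
    ]

    seasons = sorted({c.season for c in curves})
    dr_by_season = {
        s: curves_to_dose_response(corrected, layout, season=s, at_h=cfg.season_h)
        for s in seasons
    }

    # --- Hill fit, MIC and EAD on the first-season (ancestral) response ---
    dr1 = dr_by_season[seasons[0]]
    hill = growth_dose.fit_hill(dr1, n_boot=cfg.bootstrap_n, seed=cfg.seed)
    summary["mic_ic99_ug_ml"] = hill.mic
    summary["mic_ci"] = list(hill.mic_ci)

    ead_rows = []
    for s, dr in dr_by_season.items():
        # EAD per replicate at the treated doses, using the ancestral fit
        for j, dose in enumerate(dr.doses):
            for rep in range(dr.densities.shape[0]):
                val = growth_dose.ead(hill, float(dr.densities[rep, j]))
                ead_rows.append({"season": s, "dose": dose, "replicate": rep, "ead": val})
    ead_df = pd.DataFrame(ead_rows)
    ead_df.to_csv(out / "ead.tsv", sep="\t", index=False)

    # --- ROA and the inverted-U -------------------------------------------
    roa = _phenotype_roa_table(plate, layout, cfg.season_h)
    roa.to_csv(out / "roa_alpha.tsv", sep="\t", index=False)
    summ = adaptation.inverted_u_summary(roa)
    summ.dose_means.to_csv(out / "roa_dose_summary.tsv", sep="\t", index=False)
    summary["roa_classification"] = summ.classification
    summary["roa_argmax_dose"] = summ.argmax_dose

    increments = adaptation.dose_increment_change(
        dr_by_season[seasons[0]], dr_by_season[seasons[-1]], labels=["first", "last"]
    )
    increments.to_csv(out / "dose_increments.tsv", sep="\t", index=False)

    # --- coverage: relative copies, amplification fits, dose hotspots ------
    if cfg.coverage_dir is not None:
        cov_dir = Path(cfg.coverage_dir)
        manifest = pd.read_csv(cov_dir / "manifest.tsv", sep="\t")
        features = read_features(cov_dir / "features.bed")
        anc_row = manifest[manifest["role"] == "ancestral"].iloc[0]
        ancestral = read_coverage(cov_dir / anc_row["path"], sample_id="ancestral")
        samples = manifest[manifest["role"] != "ancestral"]
        amp_rows = []
        for feat in features:
            for dose, grp in samples.groupby("dose"):
                tracks = [
                    read_coverage(
                        cov_dir / r["path"],
                        sample_id=str(r["path"]),
                        dose=float(dose),
                        time=float(r["time_d"]),
                    )
                    for _, r in grp.iterrows()
                ]
                rc = genomic_selection.relative_copies(
                    tracks, feat, ancestral, stat=cfg.norm_stat
                )
                fit = genomic_selection.fit_amplification(rc)
                amp_rows.append(
                    {
                        "feature": feat.name,
                        "dose": float(dose),
                        "p1": fit.p1,
                        "p2": fit.p2,
                        "s_proxy": fit.s_proxy,
                        "converged": fit.converged,
                    }
                )
        amp_df = pd.DataFrame(amp_rows)
        amp_df.to_csv(out / "amplification_selection.tsv", sep="\t", index=False)
        hot_rows = []
        for feat_name, grp in amp_df.groupby("feature"):
            ok = grp[grp["converged"]]
            if len(ok) < 4:
                continue
            est = genomic_selection.gene_dose_hotspot(
                dict(zip(ok["dose"], ok["s_proxy"])), sd_screen=cfg.sd_screen
            )
            hot_rows.append(
                {
                    "feature": feat_name,
                    "e_max": est.e_max,
                    "s_max_pred": est.s_max_pred,
                    "keep": est.keep_flag,
                    "shape": est.shape,
                }
            )
        pd.DataFrame(hot_rows).to_csv(out / "amplification_hotspots.tsv", sep="\t", index=False)
        summary["amplification_hotspots"] = {
            r["feature"]: r["e_max"] for r in hot_rows
        }

    # --- SNP selection and parallelism -------------------------------------
    if cfg.snp_path is not None:
        snps = read_snps(cfg.snp_path)
        trajs = genomic_selection.filter_snp_trajectories(snp_table_to_trajectories(snps))
        snp_rows = []
        for tr in trajs:
            fit = genomic_selection.fit_snp_selection(tr)
            snp_rows.append(
                {
                    "position": tr.position,
                    "gene": tr.gene,
                    "dose": tr.dose,
                    "p": fit.p,
                    "s": fit.s,
                    "converged": fit.converged,
                }
            )
        snp_df = pd.DataFrame(snp_rows)
        snp_df.to_csv(out / "snp_selection.tsv", sep="\t", index=False)
        if len(snp_df):
            final = snps.loc[snps.groupby(["gene", "dose"])["time_d"].idxmax()]
            by_gene = {
                g: grp.sort_values("dose")["freq"].to_numpy()
                for g, grp in final.groupby("gene")
                if grp["dose"].nunique() == snps["dose"].nunique()
            }
            par = genomic_selection.parallelism(by_gene)
            pd.DataFrame(
                [
                    {
                        "gene": r.gene,
                        "lambda_star": r.lambda_star,
                        "P": r.P,
                        "p_coeff": r.p_coeff,
                        "parallel": r.parallel_flag,
                    }
                    for r in par
                ]
            ).to_csv(out / "parallelism.tsv", sep="\t", index=False)
            summary["n_parallel_genes"] = int(sum(r.parallel_flag for r in par))
        else:
            summary["n_parallel_genes"] = 0
    else:
        summary["n_parallel_genes"] = None

    summary_json = json.dumps(summary, indent=2, sort_keys=True, default=float)
    (out / "summary.json").write_text(summary_json)
    return summary
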