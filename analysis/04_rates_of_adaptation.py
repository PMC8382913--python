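#!/usr/bin/env python
"""Rates of adaptation across the dose gradient: alpha per replicate, the
inverted-U classification with its hotspot dose, dose-increment significance
tests, and the instrument-oscillation periodogram.

Reads results/simulated/; writes results/roa_alpha.tsv,
results/roa_dose_summary.tsv, results/dose_increments.tsv and
results/periodogram.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ampliscope import growth_dose
from ampliscope.adaptation import (
    PhenotypeSeries,
    dose_increment_change,
    inverted_u_summary,
    oscillation_periodogram,
    roa_alpha,
)
from ampliscope.pipeline_io import curves_to_dose_response, read_plate
from ampliscope.synthetic_data import season_endpoint_series

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"

plate = pd.read_csv(SIM / "plate.tsv", sep="\t")
layout = pd.read_csv(SIM / "layout.tsv", sep="\t")

series = season_endpoint_series(plate, layout)
roa = pd.DataFrame(
    {"dose": s.dose, "replicate": s.replicate, "value": roa_alpha(s).value}
    for s in series
)
roa.to_csv(OUT / "roa_alpha.tsv", sep="\t", index=False)

summ = inverted_u_summary(roa)
summ.dose_means.to_csv(OUT / "roa_dose_summary.tsv", sep="\t", index=False)
print(f"dose profile of alpha: {summ.classification}, hotspot {summ.argmax_dose} ug/ml")
print(summ.dose_means.round(5).to_string(index=False))

# density changes between adjacent doses at the first and last season
curves = read_plate(SIM / "plate.tsv", SIM / "layout.tsv")
fits = {}
for c in curves:
    try:
        fits[(c.well_id, c.season)] = growth_dose.fit_growth_models(c)
    except (RuntimeError, ValueError):
        pass
corrected = [
    growth_dose.blank_correct(c, fits[(c.well_id, c.season)])
    for c in curves
    if (c.well_id, c.season) in fits
]
seasons = sorted({c.season for c in corrected})
inc = dose_increment_change(
    curves_to_dose_response(corrected, layout, season=seasons[0]),
    curves_to_dose_response(corrected, layout, season=seasons[-1]),
    labels=["first", "last"],
)
inc.to_csv(OUT / "dose_increments.tsv", sep="\t", index=False)
n_sig = int(inc["significant"].sum())
print(f"{n_sig}/{len(inc)} adjacent-dose increments significant (raw P<0.05)")

# periodogram of the drug-free first-season trace, averaged over replicates
# (the instrument oscillation is coherent across wells, read noise is not);
# the reading at exactly 24 h belongs to the next, freshly diluted season
wells = layout.loc[layout["dose_ug_ml"] == 0.0, "well"]
sub = plate[plate["well"].isin(wells) & (plate["time_h"] < 24.0 - 1e-9)]
mean_trace = sub.groupby("time_h")["od600"].mean()
s = PhenotypeSeries("od", 0.0, 0, mean_trace.index.to_numpy(), mean_trace.to_numpy())
spectrum, dominant = oscillation_periodogram(s, detrend="model")
spectrum.to_csv(OUT / "periodogram.tsv", sep="\t", index=False)
print(f"dominant oscillation wavelengths (h): {np.round(dominant, 3)}")
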