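#!/usr/bin/env python
"""Simulate the serial-transfer treatment assay (7 seasons, 8 replicates,
erythromycin-like doses 0-50 ug/ml) and record the ground truth.

Writes results/simulated/{plate.tsv,layout.tsv,ground_truth.json}.
"""

import json
from pathlib import Path

import numpy as np

from ampliscope.pipeline_io import write_plate
from ampliscope.synthetic_data import SerialTransferConfig, simulate_serial_transfer

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 1
cfg = SerialTransferConfig(seed=SEED)
plate, layout, truth = simulate_serial_transfer(cfg)
write_plate(plate, layout, OUT / "plate.tsv", OUT / "layout.tsv")

(OUT / "ground_truth.json").write_text(
    json.dumps(
        {
            "seed": SEED,
            "fastest_dose_ug_ml": truth.fastest_dose,
            "alpha_by_dose": dict(
                zip(map(float, truth.doses), map(float, truth.alpha_by_dose))
            ),
            "final_resistant_fraction_by_dose": dict(
                zip(map(float, truth.doses), map(float, truth.resistant_fraction[:, -1]))
            ),
        },
        indent=2,
    )
)

print(f"simulated {len(layout)} wells x {cfg.n_seasons} seasons at seed {SEED}")
print("noise-free adaptation rate by dose (per h):")
for d, a in zip(truth.doses, truth.alpha_by_dose):
    bar = "#" * int(round(a / max(truth.alpha_by_dose.max(), 1e-12) * 40))
    print(f"  {d:5.0f} ug/ml  {a: .5f}  {bar}")
print(f"ground-truth fastest-adapting dose: {truth.fastest_dose} ug/ml")
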