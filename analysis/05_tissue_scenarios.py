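#!/usr/bin/env python
"""Individualization scenarios: body-composition changes under BID dosing.

Grows or shrinks muscle and adipose volumes (with proportional plasma flow)
and compares the plasma oscillation amplitude and mean over the final
dosing interval against the 70 kg reference subject.
"""

from pathlib import Path

import pandas as pd

import metpbpk as mp
from metpbpk.pk_metrics import oscillation_metrics

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

human = mp.build_human_model()
schedule = mp.DoseSchedule.repeated(500.0, 8, 12.0)

SCENARIOS = {
    "reference": None,
    "muscle_plus_10L": ("muscle", 10_000.0),
    "muscle_minus_10L": ("muscle", -10_000.0),
    "adipose_plus_10L": ("adipose", 10_000.0),
    "adipose_minus_10L": ("adipose", -10_000.0),
}

rows = []
for label, change in SCENARIOS.items():
    model = human if change is None else mp.scenario_modify_tissue(human, *change)
    result = mp.simulate(model, schedule, 108.0)
    amp, mean = oscillation_metrics(result, "venous_plasma", tau=12.0)
    rows.append({"scenario": label, "plasma_mean_nmol_ml": mean,
                 "plasma_amplitude_nmol_ml": amp,
                 "amplitude_over_mean": amp / mean})

table = pd.DataFrame(rows)
ref = table.loc[table["scenario"] == "reference", "plasma_mean_nmol_ml"].iloc[0]
table["mean_vs_reference"] = table["plasma_mean_nmol_ml"] / ref
table.to_csv(RESULTS / "tissue_scenarios.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nlarger distribution volumes damp the peak-trough swing; the "
      "interval mean barely moves because clearance is unchanged.")
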