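#!/usr/bin/env python
"""Repeated human dosing: 500 mg twice daily, 8 doses, followed to 108 h.

Reports course-wide Cmax, interval Cmean, steady-state times and the slow
accumulation of the red-blood-cell pool.
"""

from pathlib import Path

import pandas as pd

import metpbpk as mp
from metpbpk.pk_metrics import multidose_summary, steady_state_time, summary_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

human = mp.build_human_model()
schedule = mp.DoseSchedule.repeated(500.0, 8, 12.0)
result = mp.simulate(human, schedule, 108.0)
print(f"mass balance: {mp.mass_balance(result):.2e}")

summary_table(result, 500.0, multidose_tau=12.0).to_csv(
    RESULTS / "human_bid_summary.csv", index=False)

rows = []
for tissue in ("venous_plasma", "rbc", "muscle", "liver", "kidney"):
    s = multidose_summary(result, tissue, tau=12.0)
    rows.append({
        "tissue": tissue, "cmax_nmol_ml": s.cmax, "tmax_h": s.tmax,
        "cmean_nmol_ml": s.cmean,
        "steady_state_h": steady_state_time(result, tissue, tau=12.0),
        "steady_state_reached": s.steady_state_reached,
    })
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "human_bid_steady_state.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nplasma reaches steady state within ~2 days; the red-blood-cell "
      "pool is still accumulating when dosing stops and peaks only after "
      "the last dose.")
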