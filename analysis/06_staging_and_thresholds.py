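#!/usr/bin/env python
"""Staging regression, threshold optimization, tension, and cohort rates.

Refits the exponential growth law from the series written by
01_simulate_embryos.py and stages example cell counts; scans the
initial-cell-count threshold on the synthetic cohort (expected optimum:
110 cells); estimates cortical tension from a noisy synthetic aspiration
series; and computes the published outcome proportions from their counts.
Writes results/threshold_scan.csv and results/staging.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from periquant import io, mechanics
from periquant.synthetic import make_aspiration_series

Path("results").mkdir(exist_ok=True)

# --- exponential staging ----------------------------------------------------
growth = pd.read_csv("results/synthetic/growth_total.csv")
reg = mechanics.fit_exponential_growth(growth["hours"], growth["count"])
print(f"growth fit: y = {reg.a:.2f} e^({reg.b:.4f} x), R^2 = {reg.r_squared:.3f} "
      f"(x in hours past {reg.time_origin})")
staged = pd.DataFrame(
    {
        "count": [75, 150, 300, 500],
        "embryonic_day": [
            mechanics.stage_from_count(c, reg) for c in (75, 150, 300, 500)
        ],
    }
)
staged.to_csv("results/staging.csv", index=False)
print(staged.to_string(index=False, float_format=lambda x: f"{x:.2f}"))

# --- threshold scan ---------------------------------------------------------
cohort = io.read_cohort("results/synthetic/cohort.csv")
scan = mechanics.threshold_scan(cohort)
scan.table.to_csv("results/threshold_scan.csv", index=False)
best = scan.table.loc[scan.table["threshold"] == scan.optimum].iloc[0]
print(f"\nthreshold scan (n={len(cohort)}): optimum >= {scan.optimum} cells, "
      f"accuracy {best['accuracy']:.3f}")

# --- cortical tension -------------------------------------------------------
series = make_aspiration_series(5e-4, rp_um=3.5, rc_um=10.0, n=44, noise_cv=0.05, seed=0)
gammas = [mechanics.cortical_tension(m) for m in series]
print(f"\ncortical tension from 44 aspirations: "
      f"{np.mean(gammas) * 1e3:.3f} +/- {np.std(gammas) * 1e3:.3f} mN/m "
      f"(true 0.500 mN/m)")

# --- published outcome proportions -------------------------------------------
d2 = mechanics.success_rates(23, 17, 18, 12)
print(f"\negg-cylinder formation: {100 * d2['egg_cylinder_rate']:.0f}% (17/23)")
print(f"AVE asymmetry given cylinder: {100 * d2['ave_rate_given_cylinder']:.0f}% (12/18)")
print(f"overall success: {100 * d2['overall_rate']:.0f}%")
print(f"temporal delay (36 h in utero equivalent per 48 h culture): "
      f"{100 * mechanics.temporal_delay(36.0, 48.0):.0f}%")
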