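#!/usr/bin/env python
"""Quantify the proximal-distal signaling landscape of the synthetic EPI.

Annotates each EPI cell high/low by the Hoechst-normalized marker median
split, computes the percentage of high cells in the proximal and distal
halves (with and without the 20% lateral trim), checks the annotation
against the generator's ground-truth states, and computes a 1-degree
angular profile on a synthetic two-channel image with one bright sector.
Writes results/signaling_fractions.csv and results/angular_profile.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from periquant import io, signaling
from periquant.model import Tissue

(frame,) = io.read_cell_table("results/synthetic/signaling.csv")
states = np.load("results/synthetic/signaling_truth.npy")

ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker", "hoechst")
recovered = np.array([a.is_high for a in ann])
agreement = float((recovered == states).mean())

prox, dist = signaling.proximal_distal_fractions(frame, ann)
prox_t, dist_t = signaling.proximal_distal_fractions(
    frame, ann, trim=True, trim_fraction=0.20
)

Path("results").mkdir(exist_ok=True)
pd.DataFrame(
    [
        {"trim": False, "percent_high_proximal": prox, "percent_high_distal": dist},
        {"trim": True, "percent_high_proximal": prox_t, "percent_high_distal": dist_t},
    ]
).to_csv("results/signaling_fractions.csv", index=False)

print(f"median-split vs ground-truth state agreement: {agreement:.3f}")
print(f"untrimmed: proximal {prox:.1f}% high, distal {dist:.1f}% high")
print(f"trimmed:   proximal {prox_t:.1f}% high, distal {dist_t:.1f}% high")

# angular profile on a synthetic landscape with a bright 30-degree sector
h = w = 201
yy, xx = np.mgrid[:h, :w]
marker = np.full((h, w), 10.0)
wedge = (yy < 95) & (np.abs(xx - 100) < (100 - yy) * 0.27)
marker[wedge] += 40.0
reference = np.full((h, w), 10.0)
prof = signaling.angular_profile(marker, reference, (100, 100), 80)
pd.DataFrame(
    {"angle_deg": prof.angle_deg, "ratio_deviation": prof.ratio_deviation}
).to_csv("results/angular_profile.csv", index=False)
peak = int(prof.angle_deg[np.argmax(prof.ratio_deviation)])
print(f"angular profile: peak deviation at {peak} deg "
      f"(bright sector centered on 0 deg), mean deviation "
      f"{prof.ratio_deviation.mean():.2e}")
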