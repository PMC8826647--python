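#!/usr/bin/env python
"""Generate the synthetic inputs used by the downstream analysis steps.

Writes, under results/synthetic/:
  - cells_d2.csv         18 D2-like egg cylinders (12 with a one-sided AVE
                         patch, 6 rotationally symmetric)
  - signaling.csv        one EPI frame with a 0.8 proximal / 0.2 distal
                         high-state gradient
  - cohort.csv           500 embryos with logistic count-dependent success
                         (midpoint 110 cells)
  - growth_total.csv     noiseless total-count series, a=75.06, b=0.0712/h
  - labels.tif           three rasterized ellipsoidal cells at 0.5 um voxels
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from periquant import io
from periquant.synthetic import (
    EggCylinderSpec,
    GradientSpec,
    make_cohort,
    make_egg_cylinder,
    make_growth_series,
    make_label_volume,
    make_signaling_frame,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(SEED)

# --- D2-like cohort of egg cylinders ---------------------------------------
frames = []
for i in range(12):
    frames.append(
        make_egg_cylinder(
            EggCylinderSpec(seed=int(rng.integers(2**31)), ave_concentration=8.0)
        )
    )
for i in range(6):
    frames.append(
        make_egg_cylinder(
            EggCylinderSpec(
                seed=int(rng.integers(2**31)),
                ave_concentration=0.0,
                ave_axial_offset=0.0,
                n_ave=30,
                n_ve=100,
            )
        )
    )
for i, fr in enumerate(frames):
    fr.embryo_id = f"d2_{i:02d}"
io.write_cell_table(frames, OUT / "cells_d2.csv")
print(f"wrote {len(frames)} embryos (12 patched + 6 symmetric) -> cells_d2.csv")

# --- EPI signaling gradient -------------------------------------------------
frame, states = make_signaling_frame(GradientSpec(seed=SEED, n_epi=300))
io.write_cell_table([frame], OUT / "signaling.csv")
np.save(OUT / "signaling_truth.npy", states)
print(f"wrote {states.size} EPI cells, true high fraction {states.mean():.2f}")

# --- cohort, growth series --------------------------------------------------
cohort, truth = make_cohort(500, logistic_midpoint=110.0, logistic_slope=0.25, seed=SEED)
io.write_cohort(cohort, OUT / "cohort.csv")
print(f"wrote cohort n=500, success rate {cohort.outcomes().mean():.2f} "
      f"(logistic midpoint {truth['logistic_midpoint']:.0f})")

hours, counts = make_growth_series(75.06, 0.0712, np.linspace(0, 48, 9))
pd.DataFrame({"hours": hours, "count": counts}).to_csv(
    OUT / "growth_total.csv", index=False
)
print("wrote noiseless growth series (9 timepoints over 48 h)")

# --- label volume -----------------------------------------------------------
vol, truths = make_label_volume(
    [
        ((20.0, 20.0, 20.0), (10.0, 5.0, 5.0), None),
        ((20.0, 20.0, 50.0), (10.0, 8.0, 4.0), None),
        ((20.0, 55.0, 35.0), (8.0, 8.0, 8.0), None),
    ],
    (0.5, 0.5, 0.5),
    (80, 140, 140),
)
io.write_label_volume(vol, OUT / "labels.tif")
print(f"wrote label volume with {len(truths)} cells -> labels.tif")
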