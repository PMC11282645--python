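#!/usr/bin/env python
"""Repeatability analysis and figures from the saved study outputs.

Reads the per-repetition spatial-temporal maps written by
03_run_injection_study.py, recomputes repetition statistics and
Bland-Altman agreement from the files (exercising the CSV round trip), and
renders the spatial-temporal heatmaps with isoconcentration contours, the
SD map and the Bland-Altman plot for the flushed L4/L5 protocol.
"""

import sys
from pathlib import Path

import numpy as np

from csfdispersion.quantify import SpatioTemporalMap, auc_profile
from csfdispersion.stats import bland_altman, repetition_stats
from csfdispersion import viz

STUDY = Path("results/study")
OUT = Path("results/figures")
if not STUDY.exists():
    sys.exit("run analysis/03_run_injection_study.py first")
OUT.mkdir(parents=True, exist_ok=True)

PROTOCOL = "2G2"
maps = [
    SpatioTemporalMap.from_csv(p)
    for p in sorted(STUDY.glob(f"map_{PROTOCOL}_rep*.csv"))
]
print(f"{PROTOCOL}: {len(maps)} repetition maps loaded from {STUDY}/")

rs = repetition_stats(maps)
print(f"max SD = {rs.max_sd:.2f} uM; max 95% CI = {rs.max_ci:.2f} uM; "
      f"%DR = {rs.percent_dynamic_range:.2f}%")

ba = bland_altman(np.stack([m.c for m in maps]))
print(f"Bland-Altman: mean difference {ba.mean_difference:.2e} uM, "
      f"limits of agreement [{ba.limits[0]:.2f}, {ba.limits[1]:.2f}] uM")

for rep, m in enumerate(maps):
    viz.plot_spatiotemporal(m, OUT / f"stmap_{PROTOCOL}_rep{rep}.png",
                            title=f"{PROTOCOL} repetition {rep}")
viz.plot_sd_map(maps[0].z_centers, maps[0].t_frames, rs.sd_map,
                OUT / f"sdmap_{PROTOCOL}.png",
                title=f"{PROTOCOL} repetition SD")
viz.plot_bland_altman(ba, OUT / f"bland_altman_{PROTOCOL}.png",
                      title=f"{PROTOCOL} repetitions vs mean")

profiles = {}
for path in sorted(STUDY.glob("map_*_rep0.csv")):
    name = path.stem.split("_")[1]
    m = SpatioTemporalMap.from_csv(path)
    profiles[name] = auc_profile(m, (0.0, 3.0))
viz.plot_auc_profiles(profiles, OUT / "auc_0_3h_profiles.png",
                      title="AUC 0-3 h, repetition 0 of each protocol")

print(f"figures in {OUT}/")
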