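#!/usr/bin/env python
"""Standstill biomechanics: weight fractions, CoS, and posture decay fits.

Summarizes every accepted load trial (5 s standstill rule), then fits the
exponential decay of forelimb load fraction against head height and the
linear CoS-vs-angle map (results/cohort/load_summary.csv).
"""

import json
from pathlib import Path

import pandas as pd

from limbcoord.cli import cmd_loads
from limbcoord.config import PipelineConfig
from limbcoord.cos_mapping import build_cos_map

# bulky per-trial workspace lives under scratch/; small summaries under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cfg = PipelineConfig(n_mice=4, strides_per_trial=30, seed=1)
    cmd_loads(cfg, OUT)
    df = pd.read_csv(OUT / "load_summary.csv")
    print(f"{len(df)} accepted load trials")
    print("mean CoS_AP (cm) by head height:")
    print(df[df.slope_deg == 0].groupby("head_height_mm")["cos_ap_cm"].mean().round(3))
    decay = OUT / "forelimb_fraction_decay.json"
    if decay.exists():
        print("forelimb-fraction decay fit:", json.loads(decay.read_text()))
    cmap = build_cos_map(df[df.slope_deg == 0.0], "snout_hump_angle_deg")
    print(f"CoS_AP vs snout-hump angle: {cmap.slope:.4f} cm/deg over {cmap.covariate_range}")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "load_summary.csv").write_bytes((OUT / "load_summary.csv").read_bytes())
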