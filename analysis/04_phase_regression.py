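#!/usr/bin/env python
"""Circular statistics of homolateral phase: mixtures and regression.

Fits 1-4 component von Mises mixtures (BIC selection, unimodality
verdict) to the pooled homolateral phases, then the circular-linear
regression of phase on snout-hump angle, speed and slope with per-mouse
offsets and bootstrap intervals (results/cohort/mixture_fit.json,
phase_regression.json).
"""

import json
from pathlib import Path

from limbcoord.cli import cmd_mixture, cmd_regress
from limbcoord.config import PipelineConfig

# bulky per-trial workspace lives under scratch/; small summaries under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cfg = PipelineConfig(n_mice=4, strides_per_trial=30, seed=1, n_boot=200)
    cmd_mixture(cfg, OUT)
    cmd_regress(cfg, OUT)
    mix = json.loads((OUT / "mixture_fit.json").read_text())
    print(
        f"mixture: {mix['selected']['n_components']} component(s), "
        f"unimodal={mix['unimodal']} (criterion {mix['criterion']})"
    )
    RESULTS.mkdir(exist_ok=True)
    for name in ("mixture_fit.json", "phase_regression.json"):
        (RESULTS / name).write_bytes((OUT / name).read_bytes())
    reg = json.loads((OUT / "phase_regression.json").read_text())
    for name, beta in zip(reg["covariate_names"], reg["beta"]):
        lo, hi = reg["intervals"][name]
        star = "*" if reg["significant"][name] else "n.s."
        print(f"  {name}: beta={beta:+.4f} rad/unit, 95% CI ({lo:+.4f}, {hi:+.4f}) {star}")
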