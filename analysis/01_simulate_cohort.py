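#!/usr/bin/env python
"""Generate the synthetic cohort: pose-tracking and load-cell trials.

Writes trajectory trials (tidy CSV + TOML metadata + ground-truth JSON)
and standstill load trials for every mouse under head-height and
surface-slope conditions, into the scratch/cohort workspace consumed by
the later stages.
"""

from pathlib import Path

from limbcoord.cli import cmd_simulate
from limbcoord.config import PipelineConfig

# bulky per-trial workspace lives under scratch/; small summaries under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cfg = PipelineConfig(n_mice=4, strides_per_trial=30, seed=1)
    OUT.mkdir(parents=True, exist_ok=True)
    cmd_simulate(cfg, OUT)
    n_traj = len(list((OUT / "trajectories").glob("*.toml")))
    n_load = len(list((OUT / "loads").glob("*.toml")))
    print(f"wrote {n_traj} trajectory trials and {n_load} load trials to {OUT}")
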