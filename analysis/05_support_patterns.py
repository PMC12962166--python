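#!/usr/bin/env python
"""Limb support patterns and their principal axes.

Computes per-stride support-category time fractions, runs a centered PCA
per hindlimb coordination category, and regresses retained PC
projections on posture covariates (results/cohort/support_*.csv).
"""

from pathlib import Path

import pandas as pd

from limbcoord.cli import cmd_support
from limbcoord.config import PipelineConfig

# bulky per-trial workspace lives under scratch/; small summaries under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cfg = PipelineConfig(n_mice=4, strides_per_trial=30, seed=1)
    cmd_support(cfg, OUT)
    prof = pd.read_csv(OUT / "support_profiles.csv")
    cats = [c for c in prof.columns if c in (
        "four_limb", "three_limb", "diagonal", "homologous_fore",
        "homologous_hind", "homolateral", "single_limb", "no_contact")]
    print(f"{len(prof)} strides; mean support fractions:")
    print(prof[cats].mean().round(3).sort_values(ascending=False))
    reg = OUT / "support_pc_regression.csv"
    if reg.exists():
        RESULTS.mkdir(exist_ok=True)
        (RESULTS / reg.name).write_bytes(reg.read_bytes())
        sig = pd.read_csv(reg).query("significant")
        print(f"{len(sig)} significant PC-covariate relations")
        if len(sig):
            print(sig[["category", "pc", "covariate", "estimate", "pvalue"]].to_string(index=False))
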