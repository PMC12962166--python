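"""Pipeline configuration: every analysis constant in one place.

All numeric rules of the pipeline (likelihood inclusion thresholds, the
locomotion speed threshold, the dual-landmark consistency tolerance, KDE
hyperparameters, phase category bands, the standstill minimum, the VIF
screen, bootstrap sizes and seeds) live here as defaults rather than
being hard-coded in logic, and round-trip through TOML unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field, fields

import numpy as np

from . import io

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # tracking inclusion
    likelihood_min: float = 0.95
    snout_hump_min_frac: float = 0.90
    ref_limb_min_frac: float = 0.80
    # locomotion / strides
    speed_threshold_cm_s: float = 1.0
    consistency_tol_rad: float = 0.1 * np.pi
    phase_band_rad: float = 0.2 * np.pi
    # densities and mixtures
    kde_kappa: float = 10.0
    kde_bins: int = 200
    mixture_max_components: int = 4
    min_strides_per_category: int = 20
    # load analysis
    standstill_min_s: float = 5.0
    standstill_cv_max: float = 0.05
    # regression
    vif_threshold: float = 5.0
    n_boot: int = 500
    # synthetic cohort sizes (simulate subcommand)
    n_mice: int = 4
    strides_per_trial: int = 30
    head_heights: list = field(default_factory=lambda: [32.0, 42.0, 47.0, 57.0])
    slopes: list = field(default_factory=lambda: [-40.0, 0.0, 40.0])
    speed_cm_s: float = 20.0
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("likelihood_min", 0.0 <= self.likelihood_min <= 1.0),
            ("snout_hump_min_frac", 0.0 <= self.snout_hump_min_frac <= 1.0),
            ("ref_limb_min_frac", 0.0 <= self.ref_limb_min_frac <= 1.0),
            ("speed_threshold_cm_s", self.speed_threshold_cm_s >= 0),
            ("consistency_tol_rad", 0 < self.consistency_tol_rad <= np.pi),
            ("phase_band_rad", 0 < self.phase_band_rad < np.pi / 2),
            ("kde_kappa", self.kde_kappa > 0),
            ("kde_bins", self.kde_bins >= 8),
            ("standstill_min_s", self.standstill_min_s > 0),
            ("vif_threshold", self.vif_threshold > 1),
            ("n_boot", self.n_boot >= 0),
            ("n_mice", self.n_mice >= 1),
            ("strides_per_trial", self.strides_per_trial >= 2),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError("invalid configuration fields: " + ", ".join(bad))

    def to_toml(self, path):
        io.write_toml(asdict(self), path)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = io.read_toml(path)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError("unknown configuration fields: " + ", ".join(sorted(unknown)))
        return cls(**raw)

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
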