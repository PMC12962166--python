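"""Mapping covariate effects on phase into center-of-support shifts.

Load-cell trials give, per trial type, a (near-)linear relation between
the anteroposterior center of support (CoS, cm) and a posture covariate
(snout-hump angle, or surface slope). Composing the fitted
phase-vs-covariate regression with the inverse of that relation
expresses the homolateral phase shift per cm of CoS displacement — a
common currency in which head-height-type and slope-type manipulations
can be compared: if anteroposterior load distribution is the operative
variable, the two composed curves must agree.

:func:`run_cos_phase_equivalence` builds that comparison end to end on a
synthetic cohort constructed so a 0.4 cm posterior CoS shift corresponds
to a quarter-phase (0.25 pi rad) more synchronized homolateral
coordination, and measures how well the full pipeline recovers it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import kinematics, loadcells, strides
from .circstats import CircRegressionFit, circ_linear_regression
from .synthetic import CohortConfig, generate_load_trial, generate_trajectory_trial

__all__ = [
    "CoSMap",
    "build_cos_map",
    "phase_shift_per_cos",
    "equivalence_config",
    "run_cos_phase_equivalence",
]


@dataclass
class CoSMap:
    """Linear CoS_AP (cm) vs covariate relation with per-mouse offsets."""

    covariate: str
    slope: float  # cm per covariate unit
    intercept: float  # population intercept
    mouse_offsets: dict  # mouse_id -> additive offset (cm)
    covariate_range: tuple  # (lo, hi) fitted support
    n_trials: int

    def predict(self, x, allow_extrapolation: bool = False):
        x = np.asarray(x, dtype=float)
        lo, hi = self.covariate_range
        if not allow_extrapolation and (np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9)):
            raise ValueError(f"covariate outside fitted range [{lo}, {hi}]")
        return self.intercept + self.slope * x

    def invert(self, cos_ap, allow_extrapolation: bool = False):
        """Covariate value producing a given CoS_AP (population curve)."""
        if self.slope == 0:
            raise ValueError("flat CoS map cannot be inverted")
        x = (np.asarray(cos_ap, dtype=float) - self.intercept) / self.slope
        lo, hi = self.covariate_range
        if not allow_extrapolation and (np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9)):
            raise ValueError("requested CoS outside the fitted covariate range")
        return x

    @property
    def cos_range(self):
        ends = self.predict([self.covariate_range[0], self.covariate_range[1]])
        return float(min(ends)), float(max(ends))


def build_cos_map(summaries: pd.DataFrame, covariate: str) -> CoSMap:
    """Least-squares linear fit of CoS_AP (cm) on a covariate.

    ``summaries`` needs columns ``cos_ap_cm``, ``mouse_id`` and the
    covariate. Per-mouse additive offsets are absorbed by mouse dummy
    variables so the slope is a within-mouse estimate; at least 4
    distinct covariate levels are required.
    """
    df = summaries.dropna(subset=["cos_ap_cm", covariate])
    levels = np.unique(np.round(df[covariate].to_numpy(dtype=float), 9))
    if levels.size < 4:
        raise ValueError(f"need >= 4 covariate levels, got {levels.size}")
    x = df[covariate].to_numpy(dtype=float)
    y = df["cos_ap_cm"].to_numpy(dtype=float)
    mice = df["mouse_id"].to_numpy()
    uniq = sorted(set(mice.tolist()))
    # design: intercept, slope, sum-to-zero mouse contrasts
    D = [np.ones_like(x), x]
    for m in uniq[:-1]:
        col = (mice == m).astype(float) - (mice == uniq[-1]).astype(float)
        D.append(col)
    D = np.column_stack(D)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    offsets = {m: float(c) for m, c in zip(uniq[:-1], coef[2:])}
    offsets[uniq[-1]] = float(-sum(offsets.values()))
    return CoSMap(
        covariate=covariate,
        slope=float(coef[1]),
        intercept=float(coef[0]),
        mouse_offsets=offsets,
        covariate_range=(float(x.min()), float(x.max())),
        n_trials=len(df),
    )


def phase_shift_per_cos(
    fit: CircRegressionFit,
    cos_map: CoSMap,
    cos_range: tuple,
    n_points: int = 41,
):
    """Compose a phase regression with a CoS map over a CoS interval.

    The fitted mean direction ``mu(x)`` is evaluated along the covariate
    values that realize a grid of CoS positions in ``cos_range``
    (which must lie inside the map's fitted support). The phase shift is
    reported relative to the most fore-loaded end (largest CoS_AP);
    a posterior CoS displacement toward synchronization gives a negative
    shift. Returns a dict with the composed curve, the net shift over the
    range, the average rad-per-cm slope, and a bootstrap distribution of
    the net shift when the fit carries bootstrap draws.
    """
    lo, hi = float(min(cos_range)), float(max(cos_range))
    grid = np.linspace(hi, lo, n_points)  # start at the fore-loaded extreme
    xs = cos_map.invert(grid)
    name = cos_map.covariate
    if name not in fit.covariate_names:
        raise ValueError(
            f"regression has no covariate {name!r}; cannot compose with this map"
        )
    j = fit.covariate_names.index(name)
    X = np.tile(fit.x_center, (n_points, 1))
    X[:, j] = xs
    mu = fit.mean_direction(X)
    # unwrapped relative curve (shift relative to the fore-loaded extreme)
    rel = np.unwrap(mu) - np.unwrap(mu)[0]
    shift = float(rel[-1])
    out = {
        "cos_grid": grid,
        "covariate_values": xs,
        "phase_curve": mu,
        "phase_shift": shift,
        "rad_per_cm": shift / (lo - hi),
        "baseline_cos": hi,
    }
    if fit.bootstrap_beta.size:
        xc = xs - fit.x_center[j]
        bb = fit.bootstrap_beta[:, j]
        bb = bb[np.isfinite(bb)]
        shifts = 2.0 * (np.arctan(np.outer(bb, xc[-1])) - np.arctan(np.outer(bb, xc[0])))
        out["bootstrap_shifts"] = shifts.ravel()
    return out


# ---------------------------------------------------------------------------
# end-to-end equivalence experiment on a constructed cohort


_QUARTER = 0.25 * np.pi
_COS_WINDOW_CM = 0.4


def equivalence_config(seed: int = 0, strides_per_trial: int = 40) -> CohortConfig:
    """Cohort constructed so phase varies linearly with CoS at 0.25 pi / 0.4 cm.

    The forelimb-load law is put in its near-linear regime (small decay
    rate) and the phase-link slopes are chosen so the derivative of mean
    phase with respect to anteroposterior CoS equals ``0.25*pi / 0.4``
    rad/cm at the center of both manipulations, identically for the
    head-height (snout-hump angle) and the surface-slope pathway.
    """
    base = CohortConfig(seed=seed, strides_per_trial=strides_per_trial)
    c = _QUARTER / _COS_WINDOW_CM  # rad per cm, the built-in law
    # near-linear forelimb-fraction law: f ~= f0 + df/dh * (h - h_mid)
    k = 0.004
    dfdh = -0.22 / 25.0  # 0.22 forelimb-fraction drop over the 25 mm range
    h_mid = 44.5
    B = dfdh / (k * np.exp(-k * h_mid))
    A = 0.5 + B * np.exp(-k * h_mid)
    dcos_dh = 2 * base.foot_ap_cm * dfdh  # cm per mm head height
    dangle_dh = (base.angle_at_max_height - base.angle_at_min_height) / (
        max(base.head_heights) - min(base.head_heights)
    )
    dcos_dangle = dcos_dh / dangle_dh
    dcos_dslope = -2 * base.foot_ap_cm * base.slope_load_rate
    return replace(
        base,
        forelimb_frac_A=float(A),
        forelimb_frac_B=float(B),
        forelimb_frac_k=float(k),
        beta_angle=float(c * dcos_dangle / 2.0),
        beta_slope=float(c * dcos_dslope / 2.0),
        beta_speed=0.0,
        random_effect_sd=0.05,
    )


def _trajectory_phase_table(config, mice, plans):
    """Run the full trajectory pipeline and pool per-stride phase rows."""
    rows = []
    for mouse in mice:
        for trial, (hh, slope) in enumerate(plans):
            rec, _ = generate_trajectory_trial(
                config, mouse, (hh, slope, config.speed), trial=trial
            )
            included, clean, _ = kinematics.filter_tracking(rec)
            if not included:
                continue
            posture = kinematics.compute_posture(clean)
            table, _ = strides.build_stride_table(clean, posture)
            rows.append(table)
    return pd.concat(rows, ignore_index=True)


def _load_summary_table(config, mice, plans):
    rows = []
    for mouse in mice:
        for trial, (hh, slope) in enumerate(plans):
            weight = config.weights[mouse % len(config.weights)]
            lt, _ = generate_load_trial(config, (hh, slope), weight, mouse, trial)
            s = loadcells.summarize_load_trial(lt)
            rows.append(
                {
                    "mouse_id": s.mouse_id,
                    "cos_ap_cm": s.cos_ap_cm,
                    "snout_hump_angle_deg": s.snout_hump_angle_deg,
                    "slope_deg": s.slope_deg,
                    "head_height_mm": s.head_height_mm,
                }
            )
    return pd.DataFrame(rows)


def run_cos_phase_equivalence(
    seed: int = 0,
    n_mice: int = 6,
    strides_per_trial: int = 40,
    n_boot: int = 200,
):
    """Full synthetic reproduction of the CoS-equivalent phase-shift analysis.

    Generates load trials and trajectory trials for both manipulation
    types from the constructed cohort of :func:`equivalence_config`, runs
    the complete pipeline (tracking filters, stride segmentation,
    cross-correlation phases, CoS summaries, linear CoS maps, von Mises
    regressions), and composes phase-vs-covariate with covariate-vs-CoS
    for each trial type over a common central 0.4 cm CoS window.

    Returns a dict with per-type composed shifts (rad), their bootstrap
    spreads, the built-in true shift (-0.25 pi), and an overlap verdict.
    """
    config = equivalence_config(seed=seed, strides_per_trial=strides_per_trial)
    mice = list(range(n_mice))
    mid_h = 44.0

    # --- load maps (separate "sensor" cohort)
    hh_loads = _load_summary_table(config, mice, [(h, 0.0) for h in config.head_heights])
    sl_loads = _load_summary_table(config, mice, [(mid_h, s) for s in config.slopes])
    map_hh = build_cos_map(hh_loads, "snout_hump_angle_deg")
    map_sl = build_cos_map(sl_loads, "slope_deg")

    # --- trajectory cohorts
    hh_tab = _trajectory_phase_table(config, mice, [(h, 0.0) for h in config.head_heights])
    sl_tab = _trajectory_phase_table(config, mice, [(mid_h, s) for s in config.slopes])

    fit_hh = circ_linear_regression(
        hh_tab["phase_left_fore"].to_numpy(),
        hh_tab[["snout_hump_angle_deg"]].to_numpy(),
        covariate_names=["snout_hump_angle_deg"],
        groups=hh_tab["mouse_id"].to_numpy(),
        n_boot=n_boot,
        seed=seed + 11,
    )
    fit_sl = circ_linear_regression(
        sl_tab["phase_left_fore"].to_numpy(),
        sl_tab[["slope_deg"]].to_numpy(),
        covariate_names=["slope_deg"],
        groups=sl_tab["mouse_id"].to_numpy(),
        n_boot=n_boot,
        seed=seed + 12,
    )

    # --- common central CoS window of width 0.4 cm
    centers = []
    for m, f in ((map_hh, fit_hh), (map_sl, fit_sl)):
        j = f.covariate_names.index(m.covariate)
        centers.append(float(m.predict(f.x_center[j])))
    c0 = float(np.mean(centers))
    window = (c0 - _COS_WINDOW_CM / 2, c0 + _COS_WINDOW_CM / 2)

    comp_hh = phase_shift_per_cos(fit_hh, map_hh, window)
    comp_sl = phase_shift_per_cos(fit_sl, map_sl, window)

    def _band(comp):
        bs = comp.get("bootstrap_shifts")
        if bs is None or not len(bs):
            return (np.nan, np.nan)
        return tuple(np.quantile(bs, [0.025, 0.975]))

    band_hh, band_sl = _band(comp_hh), _band(comp_sl)
    overlap = not (band_hh[1] < band_sl[0] or band_sl[1] < band_hh[0])
    return {
        "true_shift": -_QUARTER,
        "shift_head_height": comp_hh["phase_shift"],
        "shift_slope": comp_sl["phase_shift"],
        "band_head_height": band_hh,
        "band_slope": band_sl,
        "bands_overlap": overlap,
        "cos_window": window,
        "map_head_height": map_hh,
        "map_slope": map_sl,
        "fit_head_height": fit_hh,
        "fit_slope": fit_sl,
        "n_strides_head_height": len(hh_tab),
        "n_strides_slope": len(sl_tab),
        "curve_head_height": comp_hh,
        "curve_slope": comp_sl,
    }
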