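"""Standstill leg-load biomechanics.

Per-limb weight fractions over a qualifying standstill window, the
center-of-support (CoS) summaries, the slope correction for detecting
only vertical force, head-post offload accounting, the weight-adjusted
head height normalization, and the exponential-decay fit used for
saturating posture relations.

Conventions: limb codes are RF, LF, RH, LH (right/left fore/hind). The
dimensionless CoS index is fore-minus-hind (AP) and right-minus-left
(ML) fractions, each in [-1, 1]; the cm-valued CoS is the load-weighted
average foot position and requires foot coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import LoadTrial

CHANNELS = ("RF", "LF", "RH", "LH")

__all__ = [
    "CHANNELS",
    "LoadSummary",
    "StandstillError",
    "find_standstill",
    "weight_fractions",
    "center_of_support_index",
    "center_of_support_position",
    "slope_detectable_weight",
    "offload_fraction",
    "max_comfortable_height",
    "weight_adjusted_head_height",
    "ExpDecayFit",
    "fit_exponential_decay",
    "summarize_load_trial",
]


class StandstillError(ValueError):
    """No qualifying standstill window in the trial."""


@dataclass
class LoadSummary:
    """Per-trial standstill biomechanics."""

    w_RF: float
    w_LF: float
    w_RH: float
    w_LH: float
    cos_ap_index: float
    cos_ml_index: float
    cos_ap_cm: float | None
    cos_ml_cm: float | None
    detected_fraction: float
    offload_fraction: float
    weight_adjusted_head_height: float
    mouse_id: str = "m00"
    head_height_mm: float = np.nan
    slope_deg: float = np.nan
    snout_hump_angle_deg: float = np.nan

    @property
    def fractions(self):
        return {c: getattr(self, f"w_{c}") for c in CHANNELS}


def find_standstill(
    trial: LoadTrial,
    min_duration: float = 5.0,
    window: float = 1.0,
    cv_max: float = 0.05,
):
    """Locate the longest low-variance window of total load.

    Rolling ``window``-second windows of the summed channels must have a
    coefficient of variation below ``cv_max``; the longest contiguous run
    of such windows, if at least ``min_duration`` long, is returned as a
    half-open sample-index pair. Raises :class:`StandstillError` when no
    run qualifies.
    """
    total = np.sum([trial.channels[c] for c in CHANNELS], axis=0)
    sr = trial.sample_rate
    w = max(2, int(round(window * sr)))
    n = total.size
    if n < w:
        raise StandstillError("trial shorter than one analysis window")
    kernel = np.ones(w) / w
    mean = np.convolve(total, kernel, mode="valid")
    sq = np.convolve(total**2, kernel, mode="valid")
    var = np.maximum(sq - mean**2, 0.0)
    cv = np.sqrt(var) / np.maximum(np.abs(mean), 1e-12)
    ok = cv < cv_max
    best = None
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            # windows [i, j) are quiet -> samples [i, j + w - 1)
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j + w - 1)
            i = j
        else:
            i += 1
    if best is None or (best[1] - best[0]) / sr < min_duration:
        raise StandstillError(
            f"no standstill of at least {min_duration} s (required for inclusion)"
        )
    return best


def weight_fractions(trial: LoadTrial, standstill_min: float = 5.0, **standstill_kw):
    """Per-limb fractions of total load over the standstill window.

    Returns ``(fractions, window)``; raises :class:`StandstillError` when
    the trial lacks a standstill of at least ``standstill_min`` seconds.
    """
    i0, i1 = find_standstill(trial, min_duration=standstill_min, **standstill_kw)
    means = {c: float(np.mean(trial.channels[c][i0:i1])) for c in CHANNELS}
    total = sum(means.values())
    if total <= 0:
        raise StandstillError("non-positive total load in standstill window")
    return {c: means[c] / total for c in CHANNELS}, (i0, i1)


def center_of_support_index(w):
    """Dimensionless CoS: (AP, ML) = (fore - hind, right - left) load fractions."""
    ap = w["RF"] + w["LF"] - (w["RH"] + w["LH"])
    ml = w["RF"] + w["RH"] - (w["LF"] + w["LH"])
    return float(ap), float(ml)


def center_of_support_position(w, foot_positions):
    """Load-weighted average foot position (AP_cm, ML_cm)."""
    for c in CHANNELS:
        if c not in foot_positions:
            raise ValueError(f"missing foot position for {c}")
    ap = sum(w[c] * foot_positions[c][0] for c in CHANNELS)
    ml = sum(w[c] * foot_positions[c][1] for c in CHANNELS)
    return float(ap), float(ml)


def slope_detectable_weight(weight: float, slope: float) -> float:
    """Vertical-force-detectable body weight on a slope: cos(slope) * weight."""
    if abs(slope) >= 90:
        raise ValueError("|slope| must be < 90 deg")
    return float(np.cos(np.deg2rad(slope)) * weight)


def offload_fraction(detected_total: float, weight: float, slope: float = 0.0) -> float:
    """Fraction of (cos-corrected) body weight transferred to the head post."""
    return float(1.0 - detected_total / slope_detectable_weight(weight, slope))


def max_comfortable_height(weight: float) -> float:
    """Maximum comfortable head height (mm): 24.5 + 1.25 * weight(g).

    The highest fixation at which both forefeet remain in ground contact,
    from the empirically derived linear relation.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    return 24.5 + 1.25 * weight


def weight_adjusted_head_height(physical_height: float, weight: float) -> float:
    """Dimensionless head height: (height - 24.5) / (1.25 * weight).

    Equals 1 at the mouse's maximum comfortable head height.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    return (physical_height - 24.5) / (1.25 * weight)


@dataclass
class ExpDecayFit:
    """y = A - B * exp(-k x) nonlinear least-squares fit."""

    A: float
    B: float
    k: float
    converged: bool
    rmse: float = np.nan

    def predict(self, x):
        return self.A - self.B * np.exp(-self.k * np.asarray(x, dtype=float))


def fit_exponential_decay(x, y) -> ExpDecayFit:
    """Fit ``y = A - B exp(-k x)`` with heuristic initialization.

    Initial values: A from the observed maximum, B from the difference
    between the initial y and A, k as the inverse of the mean predictor.
    Non-convergence (or an unidentifiable k on near-constant data) is
    flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor values")
    order = np.argsort(x)
    a0 = float(np.max(y))
    b0 = a0 - float(y[order[0]])
    k0 = 1.0 / max(float(np.mean(x)), 1e-9)
    if np.ptp(y) < 1e-12 * max(1.0, abs(a0)):
        return ExpDecayFit(A=float(np.mean(y)), B=0.0, k=np.nan, converged=False, rmse=0.0)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda xx, A, B, k: A - B * np.exp(-k * xx),
                x,
                y,
                p0=[a0, b0 if abs(b0) > 1e-12 else 1e-3, k0],
                maxfev=10000,
            )
    except RuntimeError:
        return ExpDecayFit(A=np.nan, B=np.nan, k=np.nan, converged=False)
    A, B, k = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((A - B * np.exp(-k * x) - y) ** 2)))
    return ExpDecayFit(A=A, B=B, k=k, converged=True, rmse=rmse)


def fit_exponential_decay_by_subject(df: pd.DataFrame, x: str, y: str, subject: str = "mouse_id"):
    """Per-subject exponential-decay fits; returns DataFrame of parameters."""
    rows = []
    for sid, sub in df.groupby(subject):
        fit = fit_exponential_decay(sub[x].to_numpy(), sub[y].to_numpy())
        rows.append({subject: sid, "A": fit.A, "B": fit.B, "k": fit.k, "converged": fit.converged})
    return pd.DataFrame(rows)


def summarize_load_trial(
    trial: LoadTrial,
    body_weight: float | None = None,
    standstill_min: float = 5.0,
    **standstill_kw,
) -> LoadSummary:
    """Full standstill summary of one load trial.

    Computes weight fractions, both CoS forms (the cm form only when foot
    positions are available), the detected fraction of cos-corrected
    body weight, the head-post offload fraction, and the weight-adjusted
    head height.
    """
    meta = trial.metadata
    weight = float(body_weight if body_weight is not None else meta["weight_g"])
    slope = float(meta.get("slope_deg", 0.0))
    head_height = float(meta.get("head_height_mm", np.nan))
    w, (i0, i1) = weight_fractions(trial, standstill_min=standstill_min, **standstill_kw)
    ap_i, ml_i = center_of_support_index(w)
    if trial.foot_positions is not None:
        ap_cm, ml_cm = center_of_support_position(w, trial.foot_positions)
    else:
        ap_cm = ml_cm = None
    detected = float(np.sum([np.mean(trial.channels[c][i0:i1]) for c in CHANNELS]))
    detectable = slope_detectable_weight(weight, slope)
    return LoadSummary(
        w_RF=w["RF"],
        w_LF=w["LF"],
        w_RH=w["RH"],
        w_LH=w["LH"],
        cos_ap_index=ap_i,
        cos_ml_index=ml_i,
        cos_ap_cm=ap_cm,
        cos_ml_cm=ml_cm,
        detected_fraction=detected / detectable,
        offload_fraction=offload_fraction(detected, weight, slope),
        weight_adjusted_head_height=weight_adjusted_head_height(head_height, weight)
        if np.isfinite(head_height)
        else np.nan,
        mouse_id=str(meta.get("mouse_id", "m00")),
        head_height_mm=head_height,
        slope_deg=slope,
        snout_hump_angle_deg=float(meta.get("snout_hump_angle_deg", np.nan)),
    )
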