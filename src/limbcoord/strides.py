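"""Stride segmentation and interlimb phase estimation.

A stride is the interval between consecutive swing onsets of a reference
limb; peaks of the (stance-drift-oriented) horizontal foot trajectory mark
swing onsets and troughs mark stance onsets. The relative phase of every
other limb is the cross-correlation lag between the two horizontal
trajectories over one stride, normalized by stride duration to [-pi, pi).
Positive phase means the other limb's trajectory matches the reference
delayed (the other limb lags the reference).

Phases estimated from the two independently tracked landmarks of a foot
must agree within 0.1 pi rad (circular distance) or the stride is
dropped; :func:`build_stride_table` applies the full per-bout procedure
and assembles the tidy per-stride table used by all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .circstats import wrap_angle, circ_dist, circ_mean
from .kinematics import PostureSeries, locomotor_bouts
from .synthetic import TrajectoryRecording, LIMBS, LANDMARKS, REFERENCE_LIMB

CONSISTENCY_TOL = 0.1 * np.pi

CATEGORY_ALTERNATING = "alternating"
CATEGORY_SYNCHRONIZED = "synchronized"
CATEGORY_ASYM_LEFT = "asymmetric_left_leading"
CATEGORY_ASYM_RIGHT = "asymmetric_right_leading"

__all__ = [
    "StrideSegmentation",
    "segment_strides",
    "estimate_period",
    "relative_phase",
    "consistency_filter",
    "duty_factor",
    "categorize_hindlimb_phase",
    "build_stride_table",
    "CONSISTENCY_TOL",
]


@dataclass
class StrideSegmentation:
    """Swing/stance onset frames and the stride intervals they delimit."""

    swing_onsets: np.ndarray  # peak frames
    stance_onsets: np.ndarray  # trough frames
    strides: list = field(default_factory=list)  # (onset, offset) half-open

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def estimate_period(x, frame_rate: float, min_lag_s: float = 0.05):
    """Median stride period (s) from the autocorrelation peak of a trajectory."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = x.size
    if n < 8 or np.std(x) < 1e-12:
        return None
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    min_lag = max(2, int(round(min_lag_s * frame_rate)))
    peaks, _ = signal.find_peaks(ac[min_lag : n // 2 + 1])
    if peaks.size == 0:
        return None
    return float((peaks[0] + min_lag) / frame_rate)


def segment_strides(
    limb_x,
    frame_rate: float,
    min_period: float | None = None,
    min_prominence: float | None = None,
) -> StrideSegmentation:
    """Segment one limb trajectory (within a locomotor bout) into strides.

    Peaks are swing onsets, troughs stance onsets; strides are the
    intervals between consecutive swing onsets, so the last partial
    stride is truncated at the final swing onset. When not given,
    ``min_period`` defaults to half the autocorrelation-estimated stride
    period and ``min_prominence`` to 20% of the trajectory range. Fewer
    than two peaks yields an empty segmentation.
    """
    x = np.asarray(limb_x, dtype=float)
    if x.size < 4 or np.ptp(x) < 1e-12:
        return StrideSegmentation(np.empty(0, int), np.empty(0, int), [])
    if min_period is None:
        period = estimate_period(x, frame_rate)
        min_period = 0.5 * period if period else None
    if min_prominence is None:
        min_prominence = 0.2 * np.ptp(x)
    distance = max(1, int(round(min_period * frame_rate))) if min_period else 1
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=min_prominence)
    troughs, _ = signal.find_peaks(-x, distance=distance, prominence=min_prominence)
    strides = [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]
    return StrideSegmentation(
        swing_onsets=peaks.astype(int), stance_onsets=troughs.astype(int), strides=strides
    )


class UndefinedPhaseError(ValueError):
    """Zero-variance window; the cross-correlation phase is undefined."""


def relative_phase(ref_x, other_x, stride, mean_subtract: bool = True) -> float:
    """Cross-correlation phase of ``other`` relative to ``ref`` over one stride.

    For a stride of duration ``d`` frames the mean-subtracted
    cross-correlation is evaluated at integer delays in [-d/2, d/2] (the
    series are padded by edge values where the window leaves the bout)
    and the argmax lag, with ties broken toward the smaller ``|lag|``, is
    converted to ``2*pi*lag/d`` wrapped to [-pi, pi). Positive phase =
    other limb lags the reference.
    """
    onset, offset = int(stride[0]), int(stride[1])
    d = offset - onset
    if d <= 0:
        raise ValueError("stride offset must exceed onset")
    half = d // 2
    ref = np.asarray(ref_x, dtype=float)
    other = np.asarray(other_x, dtype=float)
    pad = max(0, half - onset), max(0, offset + half - other.size)
    if any(pad):
        other = np.pad(other, pad, mode="edge")
        ref = np.pad(ref, pad, mode="edge")
        onset += pad[0]
        offset += pad[0]
    ref_w = ref[onset:offset]
    win = other[onset - half : offset + half]
    if np.std(ref_w) < 1e-12 or np.std(win) < 1e-12:
        raise UndefinedPhaseError("zero-variance window")
    if mean_subtract:
        ref_w = ref_w - ref_w.mean()
        win = win - win.mean()
    c = np.correlate(win, ref_w, mode="valid")  # c[m] = sum ref[t]*other[t + m - half]
    lags = np.arange(-half, half + 1)
    best = np.max(c)
    ties = np.flatnonzero(c >= best - 1e-9 * max(abs(best), 1.0))
    lag = int(lags[ties[np.lexsort((lags[ties], np.abs(lags[ties])))[0]]])
    return float(wrap_angle(2.0 * np.pi * lag / d))


def consistency_filter(phase_a: float, phase_b: float, tol: float = CONSISTENCY_TOL) -> bool:
    """Keep a stride iff the two landmark phases agree within ``tol`` (circular)."""
    return bool(abs(circ_dist(phase_a, phase_b)) <= tol)


def duty_factor(segmentation: StrideSegmentation, stride) -> float:
    """Fraction of the stride spent in stance (stance onset to next swing onset)."""
    onset, offset = int(stride[0]), int(stride[1])
    inside = [t for t in segmentation.stance_onsets if onset < t < offset]
    if not inside:
        raise ValueError("no stance onset inside stride; duty factor undefined")
    stance = inside[0]
    return float((offset - stance) / (offset - onset))


def categorize_hindlimb_phase(phase: float, band: float = 0.2 * np.pi) -> str:
    """Band classification of the left-right hindlimb phase.

    Alternating within ``pi +- band``, synchronized within ``0 +- band``,
    otherwise asymmetric with the leading side from the sign convention:
    a positive phase (right hindlimb lagging the left reference) is
    left-leading. Invariant under adding 2*pi.
    """
    p = wrap_angle(phase)
    if abs(p) >= np.pi - band:
        return CATEGORY_ALTERNATING
    if abs(p) <= band:
        return CATEGORY_SYNCHRONIZED
    return CATEGORY_ASYM_LEFT if p > 0 else CATEGORY_ASYM_RIGHT


def _limb_trajectory(rec: TrajectoryRecording, limb: str, landmark: str):
    return rec.data[f"{limb}_{landmark}"]["x"]


def _limb_mean_trajectory(rec: TrajectoryRecording, limb: str):
    return 0.5 * (_limb_trajectory(rec, limb, LANDMARKS[0]) + _limb_trajectory(rec, limb, LANDMARKS[1]))


def build_stride_table(
    rec: TrajectoryRecording,
    posture: PostureSeries,
    reference_limb: str = REFERENCE_LIMB,
    consistency_tol: float = CONSISTENCY_TOL,
    min_period: float | None = None,
    min_prominence: float | None = None,
):
    """Assemble the per-stride table for one (cleaned) trial.

    For each locomotor bout, the reference limb is segmented into strides
    and every other limb's phase is estimated twice (once per tracked
    landmark), passed through the 0.1 pi consistency filter, and averaged
    circularly. Rows failing segmentation, the consistency rule, or an
    undefined phase are dropped and accounted for in the returned log.

    Returns ``(table, drop_log)`` where ``table`` is a tidy DataFrame
    with one row per reference-limb stride.
    """
    if reference_limb not in LIMBS:
        raise ValueError(f"unknown reference limb {reference_limb!r}")
    others = [l for l in LIMBS if l != reference_limb]
    hind_pair = "right_hind" if reference_limb == "left_hind" else "left_hind"
    drop_log = {"consistency": 0, "undefined_phase": 0, "missing_duty": 0}
    rows = []
    dt = 1.0 / rec.frame_rate
    for b0, b1 in locomotor_bouts(posture.locomotion_mask):
        ref_x = _limb_mean_trajectory(rec, reference_limb)[b0:b1]
        seg = segment_strides(ref_x, rec.frame_rate, min_period, min_prominence)
        limb_segs = {
            limb: segment_strides(
                _limb_mean_trajectory(rec, limb)[b0:b1], rec.frame_rate, min_period, min_prominence
            )
            for limb in LIMBS
        }
        for onset, offset in seg.strides:
            d = offset - onset
            row = {
                "mouse_id": rec.metadata.get("mouse_id", "m00"),
                "trial_id": rec.metadata.get("trial", 0),
                "reference_limb": reference_limb,
                "onset_frame": b0 + onset,
                "offset_frame": b0 + offset,
                "duration_s": d * dt,
            }
            ok = True
            for limb in others:
                ph = []
                for mark in LANDMARKS:
                    try:
                        ph.append(
                            relative_phase(
                                _limb_trajectory(rec, reference_limb, mark)[b0:b1],
                                _limb_trajectory(rec, limb, mark)[b0:b1],
                                (onset, offset),
                            )
                        )
                    except UndefinedPhaseError:
                        drop_log["undefined_phase"] += 1
                        ok = False
                if not ok:
                    break
                if not consistency_filter(ph[0], ph[1], consistency_tol):
                    drop_log["consistency"] += 1
                    ok = False
                    break
                row[f"phase_{limb}"] = wrap_angle(circ_mean(np.array(ph)))
            if not ok:
                continue
            # duty factors: each limb's own stride containing the reference midpoint
            mid = (onset + offset) / 2.0
            duties = {}
            for limb in LIMBS:
                ls = limb_segs[limb]
                own = [s for s in ls.strides if s[0] <= mid < s[1]]
                try:
                    duties[limb] = duty_factor(ls, own[0]) if own else np.nan
                except ValueError:
                    duties[limb] = np.nan
            if any(np.isnan(v) for v in duties.values()):
                drop_log["missing_duty"] += 1
            for limb in LIMBS:
                row[f"duty_{limb}"] = duties[limb]
            fore = np.nanmean([duties["left_fore"], duties["right_fore"]])
            hind = np.nanmean([duties["left_hind"], duties["right_hind"]])
            row["duty_ratio_hind_fore"] = hind / fore if fore and not np.isnan(fore) else np.nan

            sl = slice(b0 + onset, b0 + offset)
            row["speed_cm_s"] = float(np.mean(posture.speed[sl]))
            row["snout_hump_angle_deg"] = float(np.mean(posture.snout_hump_angle[sl]))
            row["slope_deg"] = float(rec.metadata.get("slope_deg", 0.0))
            # stride length: AP displacement between consecutive stance onsets
            # of the reference foot plus integrated belt displacement (cm)
            belt_cm = float(np.sum(posture.speed[sl]) * dt)
            foot_disp = 0.0
            st_in = [t for t in seg.stance_onsets if onset <= t < offset]
            nxt = [t for t in seg.stance_onsets if t >= offset]
            if st_in and nxt:
                x = _limb_mean_trajectory(rec, reference_limb)[b0:b1]
                foot_disp = abs(x[nxt[0]] - x[st_in[0]]) / 10.0
            row["stride_length_cm"] = belt_cm + foot_disp
            row["hindlimb_phase"] = row[f"phase_{hind_pair}"]
            row["hindlimb_category"] = categorize_hindlimb_phase(row["hindlimb_phase"])
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, drop_log
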