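"""Trial-level preprocessing of pose-tracking recordings.

Covers the three gatekeeping steps that precede any stride analysis:
likelihood-based trial inclusion with linear interpolation of
low-confidence frames, the snout-hump posture angle, and the belt-speed
locomotion mask that delimits locomotor bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import TrajectoryRecording, REFERENCE_LIMB, LANDMARKS

__all__ = [
    "PostureSeries",
    "TrackingError",
    "filter_tracking",
    "snout_hump_angle",
    "locomotion_mask",
    "locomotor_bouts",
    "compute_posture",
]


class TrackingError(ValueError):
    """A required bodypart is missing or geometry is degenerate."""


@dataclass
class PostureSeries:
    """Per-frame posture and locomotion state for one trial."""

    snout_hump_angle: np.ndarray  # deg
    speed: np.ndarray  # cm/s
    locomotion_mask: np.ndarray  # bool
    frame_rate: float
    interpolated: dict = field(default_factory=dict)  # bodypart -> bool array


def filter_tracking(
    rec: TrajectoryRecording,
    likelihood_min: float = 0.95,
    snout_hump_min_frac: float = 0.90,
    ref_limb_min_frac: float = 0.80,
    reference_limb: str = REFERENCE_LIMB,
):
    """Apply the likelihood-based trial inclusion rule and clean the trial.

    A trial is included when at least ``snout_hump_min_frac`` of snout AND
    hump frames have likelihood >= ``likelihood_min`` and at least
    ``ref_limb_min_frac`` of the reference-limb frames do (checked on each
    of the foot's landmarks). Sub-threshold frames of every bodypart are
    linearly interpolated and flagged. Returns ``(included, cleaned_rec,
    report)`` where ``report`` maps bodypart -> good-frame fraction.
    """
    ref_parts = [f"{reference_limb}_{m}" for m in LANDMARKS]
    required = ["snout", "hump"] + ref_parts
    for part in required:
        if part not in rec.data:
            raise TrackingError(f"required bodypart missing: {part!r}")

    report = {}
    for part in rec.data:
        like = rec.data[part]["likelihood"]
        report[part] = float(np.mean(like >= likelihood_min))

    included = (
        report["snout"] >= snout_hump_min_frac
        and report["hump"] >= snout_hump_min_frac
        and all(report[p] >= ref_limb_min_frac for p in ref_parts)
    )

    frames = np.arange(rec.n_frames)
    cleaned = {}
    flags = {}
    for part, series in rec.data.items():
        good = series["likelihood"] >= likelihood_min
        flags[part] = ~good
        if good.all() or not good.any():
            cleaned[part] = {k: v.copy() for k, v in series.items()}
            continue
        entry = {"likelihood": series["likelihood"].copy()}
        for coord in ("x", "y"):
            v = series[coord].copy()
            v[~good] = np.interp(frames[~good], frames[good], series[coord][good])
            entry[coord] = v
        cleaned[part] = entry
    cleaned_rec = TrajectoryRecording(
        frame_rate=rec.frame_rate,
        data=cleaned,
        belt_speed=None if rec.belt_speed is None else rec.belt_speed.copy(),
        metadata=dict(rec.metadata, interpolated_flags=True),
    )
    cleaned_rec.metadata["interpolation_flags"] = flags
    return included, cleaned_rec, report


def snout_hump_angle(snout_xy, hump_xy, slope: float = 0.0):
    """Obtuse snout-hump posture angle, in degrees.

    The angle between the hump->snout vector and a surface-parallel line
    through the snout, folded into the obtuse convention: ``180 -
    |elevation|`` where the elevation is measured in surface-parallel
    coordinates (so the value is invariant to rotating the scene together
    with the surface, and to uniform scaling). A hump-snout vector
    parallel to the surface gives 180 deg.

    Accepts single points (shape ``(2,)``) or series (shape ``(n, 2)``).
    """
    snout = np.asarray(snout_xy, dtype=float)
    hump = np.asarray(hump_xy, dtype=float)
    v = snout - hump
    single = v.ndim == 1
    v = np.atleast_2d(v)
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(norms < 1e-9):
        raise TrackingError("snout and hump coincide; angle undefined")
    s = np.deg2rad(slope)
    vx = v[:, 0] * np.cos(s) + v[:, 1] * np.sin(s)
    vy = -v[:, 0] * np.sin(s) + v[:, 1] * np.cos(s)
    elev = np.degrees(np.arctan2(np.abs(vy), vx))
    ang = 180.0 - np.abs(elev)
    return float(ang[0]) if single else ang


def locomotion_mask(belt_speed, threshold: float = 1.0):
    """Boolean mask of locomotion: belt speed strictly above ``threshold`` cm/s."""
    speed = np.asarray(belt_speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise ValueError("belt speed contains non-finite values")
    return speed > threshold


def locomotor_bouts(mask):
    """Contiguous True runs of a locomotion mask as (start, stop) half-open pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def compute_posture(rec: TrajectoryRecording, speed_threshold: float = 1.0) -> PostureSeries:
    """Assemble the per-frame posture series for a cleaned trial.

    Speed comes from the belt channel when present; otherwise it falls
    back to the median rearward velocity of the reference foot during its
    stance (drift) phases.
    """
    if "snout" not in rec.data or "hump" not in rec.data:
        raise TrackingError("snout and hump required for posture computation")
    snout = np.column_stack([rec.data["snout"]["x"], rec.data["snout"]["y"]])
    hump = np.column_stack([rec.data["hump"]["x"], rec.data["hump"]["y"]])
    slope = float(rec.metadata.get("slope_deg", 0.0))
    angle = snout_hump_angle(snout, hump, slope)

    if rec.belt_speed is not None:
        speed = np.asarray(rec.belt_speed, dtype=float)
    else:
        ref = rec.data[f"{REFERENCE_LIMB}_{LANDMARKS[0]}"]["x"]
        v = np.gradient(ref) * rec.frame_rate  # mm/s along drift axis
        drift = v > 0
        v_med = np.median(v[drift]) if drift.any() else 0.0
        speed = np.full(rec.n_frames, abs(v_med) / 10.0)  # cm/s
    mask = locomotion_mask(speed, speed_threshold)
    return PostureSeries(
        snout_hump_angle=angle,
        speed=speed,
        locomotion_mask=mask,
        frame_rate=rec.frame_rate,
    )
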