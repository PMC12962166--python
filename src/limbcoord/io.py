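"""Readers and writers for the pipeline's on-disk formats.

Trajectory recordings round-trip through two CSV dialects: the
pose-estimation tool's native three-header-row layout (scorer /
bodyparts / coords with x, y, likelihood columns per bodypart) and a
tidy long format (frame, bodypart, x, y, likelihood). Trial metadata
travels in a flat TOML sidecar, load trials as plain CSV
(time_s, ch_RF, ch_LF, ch_RH, ch_LH), and ground truth / fitted models
as JSON. Format auto-detection inspects the header.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .loadcells import CHANNELS
from .synthetic import LoadTrial, TrajectoryRecording

__all__ = [
    "write_dlc_csv",
    "read_dlc_csv",
    "write_tidy_csv",
    "read_tidy_csv",
    "detect_trajectory_dialect",
    "read_trajectory_csv",
    "write_load_csv",
    "read_load_csv",
    "write_toml",
    "read_toml",
    "write_json",
]

_SCORER = "limbcoord-synthetic"


def write_dlc_csv(rec: TrajectoryRecording, path):
    """Write a recording in the three-header-row pose-tracking dialect."""
    cols = []
    arrays = []
    for part in rec.bodyparts:
        for coord in ("x", "y", "likelihood"):
            cols.append((_SCORER, part, coord))
            arrays.append(rec.data[part][coord])
    df = pd.DataFrame(
        np.column_stack(arrays), columns=pd.MultiIndex.from_tuples(cols, names=["scorer", "bodyparts", "coords"])
    )
    df.to_csv(path, index_label="frame")


def read_dlc_csv(path, frame_rate: float, belt_speed=None, metadata=None) -> TrajectoryRecording:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    data = {}
    for part in df.columns.get_level_values(1).unique():
        sub = df.xs(part, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        data[part] = {
            "x": sub["x"].to_numpy(dtype=float),
            "y": sub["y"].to_numpy(dtype=float),
            "likelihood": sub["likelihood"].to_numpy(dtype=float),
        }
    return TrajectoryRecording(
        frame_rate=frame_rate,
        data=data,
        belt_speed=None if belt_speed is None else np.asarray(belt_speed, dtype=float),
        metadata=dict(metadata or {}),
    )


def write_tidy_csv(rec: TrajectoryRecording, path):
    """Write a recording as long-format (frame, bodypart, x, y, likelihood)."""
    frames = np.arange(rec.n_frames)
    chunks = []
    for part in rec.bodyparts:
        chunks.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "bodypart": part,
                    "x": rec.data[part]["x"],
                    "y": rec.data[part]["y"],
                    "likelihood": rec.data[part]["likelihood"],
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)


def read_tidy_csv(path, frame_rate: float, belt_speed=None, metadata=None) -> TrajectoryRecording:
    df = pd.read_csv(path)
    data = {}
    for part, sub in df.groupby("bodypart", sort=False):
        sub = sub.sort_values("frame")
        data[str(part)] = {
            "x": sub["x"].to_numpy(dtype=float),
            "y": sub["y"].to_numpy(dtype=float),
            "likelihood": sub["likelihood"].to_numpy(dtype=float),
        }
    return TrajectoryRecording(
        frame_rate=frame_rate,
        data=data,
        belt_speed=None if belt_speed is None else np.asarray(belt_speed, dtype=float),
        metadata=dict(metadata or {}),
    )


def detect_trajectory_dialect(path) -> str:
    """Return 'dlc' or 'tidy' from header inspection."""
    with open(path) as fh:
        first = fh.readline()
    if "bodypart" in first and "likelihood" in first:
        return "tidy"
    return "dlc"


def read_trajectory_csv(path, frame_rate: float, belt_speed=None, metadata=None):
    if detect_trajectory_dialect(path) == "tidy":
        return read_tidy_csv(path, frame_rate, belt_speed, metadata)
    return read_dlc_csv(path, frame_rate, belt_speed, metadata)


def write_load_csv(trial: LoadTrial, path, sidecar=None):
    """Write a load trial as CSV; optionally its metadata as a TOML sidecar."""
    df = pd.DataFrame({"time_s": trial.time})
    for c in CHANNELS:
        df[f"ch_{c}"] = trial.channels[c]
    df.to_csv(path, index=False)
    if sidecar is not None:
        meta = dict(trial.metadata)
        if trial.foot_positions is not None:
            for c, (ap, ml) in trial.foot_positions.items():
                meta[f"foot_{c}_ap_cm"] = ap
                meta[f"foot_{c}_ml_cm"] = ml
        write_toml(meta, sidecar)


def read_load_csv(path, sidecar=None) -> LoadTrial:
    df = pd.read_csv(path)
    meta = {}
    foot_positions = None
    if sidecar is not None and Path(sidecar).exists():
        meta = read_toml(sidecar)
        fp = {}
        for c in CHANNELS:
            if f"foot_{c}_ap_cm" in meta:
                fp[c] = (meta.pop(f"foot_{c}_ap_cm"), meta.pop(f"foot_{c}_ml_cm"))
        foot_positions = fp or None
    return LoadTrial(
        time=df["time_s"].to_numpy(dtype=float),
        channels={c: df[f"ch_{c}"].to_numpy(dtype=float) for c in CHANNELS},
        metadata=meta,
        foot_positions=foot_positions,
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    s = str(v).replace("\\", "\\\\").replace('"', '\\"')
    return f'"{s}"'


def write_toml(mapping: dict, path):
    """Write a flat mapping (scalars and flat lists) as TOML."""
    lines = [f"{k} = {_toml_value(v)}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_json(obj, path):
    def _clean(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, dict):
            return {str(k): _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        return o

    with open(path, "w") as fh:
        json.dump(_clean(obj), fh, indent=1)
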