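"""Synthetic trajectory and load-cell trials with known ground truth.

The generator emulates the two recording modalities of a head-fixed
quadrupedal locomotion experiment:

* **Trajectory trials** — side-view pose-tracking of the four feet (two
  landmarks per foot), snout and hump at a fixed frame rate, together
  with a belt-speed channel. The reference-limb horizontal trajectory is
  a periodic stance/swing sawtooth (slow monotone drift during stance,
  rapid return during swing, smoothed by a short moving average), and
  every non-reference limb is the same waveform delayed by a true
  interlimb phase drawn from a von Mises distribution whose mean
  direction depends on covariates through the saturating link
  ``mu = mu0 + 2*atan(beta * (x - x0)) + mouse_offset``.
* **Load trials** — four vertical-force channels (one per foot) during a
  standstill, where the forelimb fraction of leg load decays
  exponentially with head height, shifts linearly with surface slope,
  and the channel sum equals ``cos(slope) * weight * (1 - offload)``
  plus zero-mean noise.

All randomness flows from one cohort seed through a counter-based
``numpy.random.SeedSequence`` scheme (spawn key = (stream, mouse, trial)),
so trials are bit-reproducible and independently regenerable. Every draw
is recorded in a :class:`GroundTruth` object so downstream estimators can
be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .circstats import wrap_angle

LIMBS = ("left_fore", "right_fore", "left_hind", "right_hind")
LANDMARKS = ("toe", "heel")
REFERENCE_LIMB = "left_hind"

_STREAM_TRAJ = 0
_STREAM_LOAD = 1
_STREAM_MOUSE = 2

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "TrajectoryRecording",
    "LoadTrial",
    "generate_trajectory_trial",
    "generate_load_trial",
    "draw_stride_phases",
    "mouse_offset",
    "angle_from_head_height",
    "LIMBS",
    "LANDMARKS",
    "REFERENCE_LIMB",
]


@dataclass
class CohortConfig:
    """Generative study conditions for a synthetic cohort.

    Defaults mirror the recording conditions of the head-fixed paradigm:
    400 fps video, 32-57 mm head heights, -40..40 deg slopes, ~4 Hz
    stride rate, moderately concentrated phases (kappa = 8 corresponds to
    a circular SD near 0.12 pi rad), and a homolateral-phase link that
    swings from near-alternation at hunched postures to quarter-phase
    more synchronized coordination at upright postures, transitioning
    around a snout-hump angle of 160 deg.
    """

    n_mice: int = 12
    strides_per_trial: int = 50
    frame_rate: float = 400.0  # Hz
    stride_period: float = 0.25  # s
    duty_factor_fore: float = 0.55
    duty_factor_hind: float = 0.60
    # homolateral phase link: mu0 rad, beta_angle rad/deg, beta_slope rad/deg,
    # beta_speed rad/(cm/s), x0 deg (snout-hump angle at the inflection)
    mu0: float = 0.80 * np.pi
    beta_angle: float = -0.030
    beta_slope: float = -0.006
    beta_speed: float = -0.001
    x0: float = 160.0
    hind_phase_mean: float = np.pi  # alternating left-right baseline
    kappa_phase: float = 8.0
    random_effect_sd: float = 0.10  # rad, per-mouse offset
    tracking_noise_sd: float = 0.5  # mm
    landmark_jitter_sd: float = 0.05  # rad, paired-landmark phase jitter
    dropout_frac: float = 0.02  # fraction of frames at likelihood 0.5
    head_heights: tuple = (32.0, 37.0, 42.0, 47.0, 52.0, 57.0)  # mm
    slopes: tuple = (-40.0, -20.0, 0.0, 20.0, 40.0)  # deg
    weights: tuple = (20.0, 22.0, 24.0, 26.0, 28.0)  # g
    speed: float = 20.0  # cm/s default belt speed
    lead_in_s: float = 0.5  # stationary belt before the locomotor bout
    # load-trial generative law
    forelimb_frac_A: float = 0.33
    forelimb_frac_B: float = -1.5  # negative: forelimb fraction decays with height
    forelimb_frac_k: float = 0.05  # 1/mm
    slope_load_rate: float = 0.0035  # forelimb-fraction change per deg slope
    offload_rate: float = 0.006  # offload fraction per mm above min head height
    load_noise_frac: float = 0.01  # channel noise SD as fraction of body weight
    lr_split_sd: float = 0.01  # per-trial left/right load split jitter
    load_sample_rate: float = 100.0  # Hz
    standstill_s: float = 6.0
    movement_lead_s: float = 2.0
    foot_ap_cm: float = 2.5  # |AP| position of fore/hind feet, cm
    foot_ml_cm: float = 1.0
    # snout-hump angle as a function of head height (linear map over range)
    angle_at_min_height: float = 140.0
    angle_at_max_height: float = 175.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.duty_factor_fore < 1 and 0 < self.duty_factor_hind < 1):
            raise ValueError("duty factors must lie in (0, 1)")
        if self.kappa_phase is not None and self.kappa_phase <= 0:
            raise ValueError("kappa_phase must be positive (or None for noise-free)")
        if self.frame_rate <= 0 or self.stride_period <= 0:
            raise ValueError("frame_rate and stride_period must be positive")

    def rng(self, stream: int, mouse: int = 0, trial: int = 0) -> np.random.Generator:
        """Counter-based per-trial RNG: SeedSequence(seed, spawn_key=(stream, mouse, trial))."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, mouse, trial))
        )


@dataclass
class GroundTruth:
    """Everything the generator drew, for parameter-recovery oracles."""

    mouse_index: int
    covariates: dict  # head_height, slope, speed, snout_hump_angle
    mouse_offset: float  # rad
    true_mu: dict  # limb pair -> mean direction used for draws
    phases: dict  # limb pair -> per-stride true phase, wrapped
    swing_onsets: dict  # limb -> frame indices
    stance_onsets: dict
    forelimb_fraction: float | None = None
    detectable_load: float | None = None
    offload_fraction: float | None = None
    cos_ap_cm: float | None = None
    foot_positions: dict | None = None

    def to_json(self, path):
        def _clean(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            return o

        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=1)


@dataclass
class TrajectoryRecording:
    """Per-trial multi-bodypart time series with likelihoods and metadata."""

    frame_rate: float
    data: dict  # bodypart -> {"x": arr mm, "y": arr mm, "likelihood": arr}
    belt_speed: np.ndarray | None  # cm/s per frame
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        first = next(iter(self.data.values()))
        return first["x"].size

    @property
    def bodyparts(self):
        return list(self.data)

    def series(self, bodypart, coord="x"):
        return self.data[bodypart][coord]


@dataclass
class LoadTrial:
    """Four-channel vertical force trial with metadata."""

    time: np.ndarray  # s
    channels: dict  # "RF","LF","RH","LH" -> force in gram-equivalents
    metadata: dict  # weight_g, head_height_mm, slope_deg, mouse_id, ...
    foot_positions: dict | None = None  # limb code -> (ap_cm, ml_cm)

    @property
    def sample_rate(self) -> float:
        return float(1.0 / np.median(np.diff(self.time)))


def angle_from_head_height(config: CohortConfig, head_height: float) -> float:
    """Linear posture map: snout-hump angle (deg) vs head height (mm)."""
    h0, h1 = min(config.head_heights), max(config.head_heights)
    a0, a1 = config.angle_at_min_height, config.angle_at_max_height
    return float(a0 + (a1 - a0) * (head_height - h0) / (h1 - h0))


def mouse_offset(config: CohortConfig, mouse_index: int) -> float:
    """Per-mouse random direction offset, reproducible from the cohort seed."""
    rng = config.rng(_STREAM_MOUSE, mouse_index, 0)
    return float(rng.normal(0.0, config.random_effect_sd))


def _link_mu(config: CohortConfig, angle, slope, speed, offset):
    eta = (
        config.beta_angle * (angle - config.x0)
        + config.beta_slope * slope
        + config.beta_speed * (speed - config.speed)
    )
    return config.mu0 + 2.0 * np.arctan(eta) + offset


def draw_stride_phases(
    config: CohortConfig,
    mouse_index: int,
    covariates,
    n_strides: int | None = None,
    trial: int = 0,
):
    """Draw per-stride true interlimb phases without rendering trajectories.

    ``covariates`` is ``(head_height_mm, slope_deg, speed_cm_s)``.
    Returns ``(phases, truth)`` where ``phases`` maps limb-pair names to
    wrapped per-stride phase arrays (relative to the left hindlimb) and
    ``truth`` is a :class:`GroundTruth` without frame-level fields. This
    is the fast path used for statistical parameter-recovery experiments;
    :func:`generate_trajectory_trial` uses the identical draws to place
    limb waveforms in time.
    """
    head_height, slope, speed = (float(v) for v in covariates)
    if not all(np.isfinite([head_height, slope, speed])):
        raise ValueError("non-finite covariates")
    n = config.strides_per_trial if n_strides is None else int(n_strides)
    angle = angle_from_head_height(config, head_height)
    offset = mouse_offset(config, mouse_index)
    mu_homo = _link_mu(config, angle, slope, speed, offset)
    mu_hind = config.hind_phase_mean
    rng = config.rng(_STREAM_TRAJ, mouse_index, trial)
    if config.kappa_phase is None or np.isinf(config.kappa_phase):
        lf = np.full(n, mu_homo)
        rh = np.full(n, mu_hind)
    else:
        lf = rng.vonmises(mu_homo, config.kappa_phase, size=n)
        rh = rng.vonmises(mu_hind, config.kappa_phase, size=n)
    phases = {
        "left_fore": wrap_angle(lf),
        "right_hind": wrap_angle(rh),
        "right_fore": wrap_angle(lf + rh),
    }
    truth = GroundTruth(
        mouse_index=mouse_index,
        covariates={
            "head_height": head_height,
            "slope": slope,
            "speed": speed,
            "snout_hump_angle": angle,
        },
        mouse_offset=offset,
        true_mu={
            "left_fore": float(wrap_angle(mu_homo)),
            "right_hind": float(wrap_angle(mu_hind)),
            "right_fore": float(wrap_angle(mu_homo + mu_hind)),
        },
        phases=phases,
        swing_onsets={},
        stance_onsets={},
    )
    return phases, truth


def _sawtooth(phase_frac, duty):
    """Periodic stance/swing waveform on [0, 1): peak (=1) at swing onset.

    The slow stance segment rises from the trough to the peak over a
    ``duty`` fraction of the cycle; the swing segment falls rapidly back.
    Coordinates are oriented so the stance drift increases x.
    """
    f = np.mod(phase_frac, 1.0)
    swing = 1.0 - duty
    out = np.where(f < swing, 1.0 - f / swing, (f - swing) / duty)
    return out


def _smooth(x, width):
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(np.pad(x, (width // 2, width - 1 - width // 2), mode="edge"), kernel, "valid")


def generate_trajectory_trial(
    config: CohortConfig,
    mouse_index: int,
    covariates,
    n_strides: int | None = None,
    trial: int = 0,
):
    """Render one pose-tracking trial and its ground truth.

    ``covariates`` is ``(head_height_mm, slope_deg, speed_cm_s)``. The
    trial contains a stationary lead-in (belt speed 0) followed by a
    single locomotor bout of ``n_strides`` reference-limb strides. Each
    foot carries two landmarks sharing the same true phase plus a small
    phase jitter; snout and hump are placed to realize the snout-hump
    angle implied by the head height. Returns ``(TrajectoryRecording,
    GroundTruth)``.
    """
    head_height, slope, speed = (float(v) for v in covariates)
    phases, truth = draw_stride_phases(config, mouse_index, covariates, n_strides, trial)
    n = truth_n = len(phases["left_fore"])
    fs, T = config.frame_rate, config.stride_period
    frames_per = int(round(T * fs))
    margin = frames_per // 2  # covers the +-d/2 correlation window of edge strides
    lead = int(round(config.lead_in_s * fs))
    n_bout = (n + 1) * frames_per + 2 * margin
    n_frames = lead + n_bout
    rng = config.rng(_STREAM_TRAJ, mouse_index, 1_000_000 + trial)  # noise stream

    t_bout = (np.arange(n_bout) - margin) / fs  # swing onsets of ref at t = k*T
    amp = max(10.0, speed * 10.0 * T * config.duty_factor_hind)  # mm per stride drift

    # reference-limb phase fraction; peaks at integer phase
    frac_ref = t_bout / T

    # per-stride phase delay for each non-reference limb, piecewise constant
    def limb_frac(pair):
        delay = np.zeros(n_bout)
        ph = phases[pair]
        stride_idx = np.clip(np.floor(frac_ref).astype(int), 0, truth_n - 1)
        delay = ph[stride_idx] / (2 * np.pi)
        return frac_ref - delay

    duty = {
        "left_hind": config.duty_factor_hind,
        "right_hind": config.duty_factor_hind,
        "left_fore": config.duty_factor_fore,
        "right_fore": config.duty_factor_fore,
    }
    baseline = {"left_fore": 30.0, "right_fore": 30.0, "left_hind": -30.0, "right_hind": -30.0}
    smooth_w = max(3, frames_per // 20)

    data = {}
    swing_onsets, stance_onsets = {}, {}
    for limb in LIMBS:
        frac = frac_ref if limb == REFERENCE_LIMB else limb_frac(limb)
        w = _smooth(_sawtooth(frac, duty[limb]), smooth_w)
        x_clean = baseline[limb] + amp * w
        # cosmetic vertical lift during swing
        swing_frac = np.mod(frac, 1.0) < (1.0 - duty[limb])
        y_clean = 3.0 * _smooth(swing_frac.astype(float), smooth_w)
        for li, mark in enumerate(LANDMARKS):
            if li == 0 or config.landmark_jitter_sd == 0:
                jit = 0.0
            else:
                jit = rng.normal(0.0, config.landmark_jitter_sd) / (2 * np.pi)
            wj = _smooth(_sawtooth(frac - jit, duty[limb]), smooth_w) if jit else w
            x = baseline[limb] + amp * wj
            x_full = np.concatenate([np.full(lead, x[0]), x])
            y_full = np.concatenate([np.full(lead, y_clean[0]), y_clean])
            noise = rng.normal(0.0, config.tracking_noise_sd, size=(2, n_frames))
            like = np.ones(n_frames)
            drop = rng.random(n_frames) < config.dropout_frac
            like[drop] = 0.5
            data[f"{limb}_{mark}"] = {
                "x": x_full + noise[0],
                "y": y_full + noise[1],
                "likelihood": like,
            }
        # ground-truth events (frame indices within the full recording)
        k = np.arange(n + 1)
        onset_frac = k if limb == REFERENCE_LIMB else k + phases[limb][np.clip(k, 0, n - 1)] / (2 * np.pi)
        onsets = lead + margin + np.round(onset_frac * frames_per).astype(int)
        swing_onsets[limb] = onsets[(onsets >= lead) & (onsets < n_frames)]
        st = onsets - int(round((1 - duty[limb]) * frames_per))
        stance_onsets[limb] = st[(st >= lead) & (st < n_frames)]

    # snout and hump realizing the requested snout-hump angle
    angle = truth.covariates["snout_hump_angle"]
    elev = np.deg2rad(180.0 - angle)
    L = 30.0  # hump-snout distance, mm
    s_rad = np.deg2rad(slope)
    # surface-frame hump->snout vector with |elevation| = 180 - angle (snout lower)
    v_surf = np.array([np.cos(elev), -np.sin(elev)]) * L
    rot = np.array([[np.cos(s_rad), -np.sin(s_rad)], [np.sin(s_rad), np.cos(s_rad)]])
    v_lab = rot @ v_surf
    snout_xy = np.array([60.0, head_height])
    hump_xy = snout_xy - v_lab
    for name, pos in (("snout", snout_xy), ("hump", hump_xy)):
        noise = rng.normal(0.0, 0.2, size=(2, n_frames))
        like = np.ones(n_frames)
        drop = rng.random(n_frames) < config.dropout_frac
        like[drop] = 0.5
        data[name] = {
            "x": np.full(n_frames, pos[0]) + noise[0],
            "y": np.full(n_frames, pos[1]) + noise[1],
            "likelihood": like,
        }

    belt = np.concatenate([np.zeros(lead), np.full(n_bout, speed)])
    truth.swing_onsets = swing_onsets
    truth.stance_onsets = stance_onsets
    rec = TrajectoryRecording(
        frame_rate=fs,
        data=data,
        belt_speed=belt,
        metadata={
            "mouse_id": f"m{mouse_index:02d}",
            "weight_g": float(config.weights[mouse_index % len(config.weights)]),
            "head_height_mm": head_height,
            "slope_deg": slope,
            "stim_freq_hz": 30.0,
            "stim_side": "left" if trial % 2 == 0 else "right",
            "trial": trial,
        },
    )
    return rec, truth


def generate_load_trial(
    config: CohortConfig,
    covariates,
    weight: float,
    mouse_index: int = 0,
    trial: int = 0,
):
    """Render one standstill load-cell trial and its ground truth.

    ``covariates`` is ``(head_height_mm, slope_deg)``. The trial has a
    high-variance movement lead-in followed by at least 5 s of
    standstill. Channel means realize: sum = cos(slope) * weight *
    (1 - offload(head_height)); forelimb fraction = A - B*exp(-k*h)
    shifted linearly by slope; left/right split 0.5 plus trial noise.
    Returns ``(LoadTrial, GroundTruth)``.
    """
    head_height, slope = (float(v) for v in covariates)
    if weight <= 0:
        raise ValueError("weight must be positive")
    if abs(slope) >= 90:
        raise ValueError("|slope| must be < 90 deg")
    rng = config.rng(_STREAM_LOAD, mouse_index, trial)

    f_fore = config.forelimb_frac_A - config.forelimb_frac_B * np.exp(
        -config.forelimb_frac_k * head_height
    )
    f_fore = float(np.clip(f_fore - config.slope_load_rate * slope, 0.02, 0.98))
    h0 = min(config.head_heights)
    offload = float(np.clip(config.offload_rate * (head_height - h0), 0.0, 0.5))
    detectable = np.cos(np.deg2rad(slope)) * weight * (1.0 - offload)
    r_fore = float(np.clip(rng.normal(0.5, config.lr_split_sd), 0.3, 0.7))
    r_hind = float(np.clip(rng.normal(0.5, config.lr_split_sd), 0.3, 0.7))
    means = {
        "RF": detectable * f_fore * r_fore,
        "LF": detectable * f_fore * (1 - r_fore),
        "RH": detectable * (1 - f_fore) * r_hind,
        "LH": detectable * (1 - f_fore) * (1 - r_hind),
    }

    sr = config.load_sample_rate
    n_move = int(round(config.movement_lead_s * sr))
    n_still = int(round(config.standstill_s * sr))
    time = np.arange(n_move + n_still) / sr
    noise_sd = config.load_noise_frac * weight
    channels = {}
    for ch, m in means.items():
        move = m + rng.normal(0.0, 20 * noise_sd, size=n_move) + 5 * noise_sd * np.sin(
            2 * np.pi * 1.5 * time[:n_move] + rng.uniform(0, 2 * np.pi)
        )
        still = m + rng.normal(0.0, noise_sd, size=n_still)
        channels[ch] = np.concatenate([move, still])

    ap, ml = config.foot_ap_cm, config.foot_ml_cm
    foot_positions = {
        "RF": (ap, ml),
        "LF": (ap, -ml),
        "RH": (-ap, ml),
        "LH": (-ap, -ml),
    }
    cos_ap_cm = ap * f_fore * 2 - ap  # = ap * (2 f_fore - 1)
    angle = angle_from_head_height(config, head_height) + float(rng.normal(0, 0.5))
    truth = GroundTruth(
        mouse_index=mouse_index,
        covariates={"head_height": head_height, "slope": slope, "snout_hump_angle": angle},
        mouse_offset=0.0,
        true_mu={},
        phases={},
        swing_onsets={},
        stance_onsets={},
        forelimb_fraction=f_fore,
        detectable_load=float(detectable),
        offload_fraction=offload,
        cos_ap_cm=float(cos_ap_cm),
        foot_positions=foot_positions,
    )
    meta = {
        "mouse_id": f"m{mouse_index:02d}",
        "weight_g": float(weight),
        "head_height_mm": head_height,
        "slope_deg": slope,
        "snout_hump_angle_deg": angle,
        "trial": trial,
    }
    return LoadTrial(time=time, channels=channels, metadata=meta, foot_positions=foot_positions), truth
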