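"""Synthetic 6-channel IMU generator for the six-activity course.

Signals are a gravity component plus a harmonic gait oscillation, slow
drift, and Gaussian noise.  Activity parameters are invented defaults
chosen for qualitative plausibility (gait frequencies between 1.5 and
2.8 Hz, jogging the most energetic, static postures distinguished by
device orientation); they make the classes learnable but, thanks to noise
and participant jitter, not trivially so.  A controlled "domain shift"
(rotated wearing orientation, scaled amplitudes, shifted cadences)
emulates cross-dataset degradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_data import (
    DEFAULT_CHANNELS,
    DEFAULT_STEP,
    DEFAULT_WINDOW_LEN,
    ActivityLabel,
    Dataset,
    LabelSpan,
    Recording,
    segment_windows,
)

__all__ = [
    "ActivityModelParams",
    "CoursePlan",
    "DomainParams",
    "default_domain",
    "default_course_plan",
    "synth_activity_segment",
    "synth_recording",
    "synth_dataset",
    "shifted_domain",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class ActivityModelParams:
    """Signal-model parameters for one activity."""

    gravity_orientation: tuple[float, float, float]
    step_frequency: float  # Hz; 0 for static postures
    accel_amplitude: tuple[float, float, float]  # m/s^2 per device axis
    gyro_amplitude: tuple[float, float, float]  # rad/s per device axis
    harmonic_weights: tuple[float, ...] = (0.6, 0.25, 0.15)
    noise_sd_accel: float = 0.4
    noise_sd_gyro: float = 0.05
    drift_sd: float = 0.15

    def __post_init__(self) -> None:
        n = math.sqrt(sum(v * v for v in self.gravity_orientation))
        if not math.isclose(n, 1.0, abs_tol=1e-6):
            raise ValueError("gravity_orientation must be a unit vector")
        if self.step_frequency < 0:
            raise ValueError("step_frequency must be >= 0")
        if sum(self.harmonic_weights) > 1.0 + 1e-9:
            raise ValueError("harmonic_weights must sum to <= 1")
        for v in self.accel_amplitude + self.gyro_amplitude:
            if v < 0:
                raise ValueError("amplitudes must be >= 0")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0 or self.drift_sd < 0:
            raise ValueError("noise/drift magnitudes must be >= 0")


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    return tuple(a / np.linalg.norm(a))


# Upright pocket carry: device top pointing down, display toward the body.
_UPRIGHT = _unit((0.1, -1.0, 0.15))
_LEAN_FWD = _unit((0.35, -1.0, 0.15))  # stair descent, slight forward lean
_LEAN_BACK = _unit((-0.2, -1.0, 0.15))  # stair ascent, slight backward lean
_SEATED = _unit((0.05, -0.5, 0.87))  # thigh roughly horizontal, ~60 deg tilt


def _default_activities() -> dict[ActivityLabel, ActivityModelParams]:
    return {
        ActivityLabel.WLK: ActivityModelParams(
            gravity_orientation=_UPRIGHT,
            step_frequency=1.9,
            accel_amplitude=(1.2, 3.0, 1.0),
            gyro_amplitude=(0.5, 0.25, 0.6),
        ),
        ActivityLabel.JOG: ActivityModelParams(
            gravity_orientation=_UPRIGHT,
            step_frequency=2.8,
            accel_amplitude=(3.5, 8.0, 2.5),
            gyro_amplitude=(1.4, 0.7, 1.6),
        ),
        ActivityLabel.UPS: ActivityModelParams(
            gravity_orientation=_LEAN_BACK,
            step_frequency=1.5,
            # enlarged vertical-axis weight: climbing is vertical work
            accel_amplitude=(1.0, 4.0, 0.8),
            gyro_amplitude=(0.7, 0.3, 0.5),
        ),
        ActivityLabel.DWS: ActivityModelParams(
            gravity_orientation=_LEAN_FWD,
            step_frequency=1.7,
            accel_amplitude=(2.2, 5.0, 1.2),
            gyro_amplitude=(0.9, 0.35, 0.7),
            harmonic_weights=(0.5, 0.35, 0.15),  # harder landings, sharper waveform
        ),
        ActivityLabel.SIT: ActivityModelParams(
            gravity_orientation=_SEATED,
            step_frequency=0.0,
            accel_amplitude=(0.0, 0.0, 0.0),
            gyro_amplitude=(0.0, 0.0, 0.0),
            noise_sd_accel=0.15,
            noise_sd_gyro=0.02,
            drift_sd=0.05,
        ),
        ActivityLabel.STD: ActivityModelParams(
            gravity_orientation=_UPRIGHT,
            step_frequency=0.0,
            accel_amplitude=(0.0, 0.0, 0.0),
            gyro_amplitude=(0.0, 0.0, 0.0),
            noise_sd_accel=0.2,
            noise_sd_gyro=0.03,
            drift_sd=0.08,
        ),
    }


@dataclass(frozen=True)
class CoursePlan:
    """Ordered (activity, duration-seconds) schedule of one course run."""

    segments: tuple[tuple[ActivityLabel, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("plan must have at least one segment")
        for _, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)

    def spans(self) -> list[LabelSpan]:
        spans = []
        t = 0.0
        for lab, dur in self.segments:
            spans.append(LabelSpan(start=t, end=t + dur, label=lab))
            t += dur
        return spans


def default_course_plan() -> CoursePlan:
    """Walk, jog, sit, stairs up, stand, stairs down — 50 s each, 300 s total."""
    order = (
        ActivityLabel.WLK,
        ActivityLabel.JOG,
        ActivityLabel.SIT,
        ActivityLabel.UPS,
        ActivityLabel.STD,
        ActivityLabel.DWS,
    )
    return CoursePlan(tuple((lab, 50.0) for lab in order))


@dataclass(frozen=True)
class DomainParams:
    """Per-activity models plus recording-domain globals."""

    activities: dict[ActivityLabel, ActivityModelParams]
    g: float = STANDARD_GRAVITY
    orientation: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))  # wearing rotation

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError("g must be positive")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a proper 3x3 rotation")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("orientation must have determinant +1")

    @property
    def rotation(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)


def default_domain() -> DomainParams:
    return DomainParams(activities=_default_activities())


def _drift(n: int, rate: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow wander: two low-frequency sinusoids with random phase, RMS ~ sd."""
    if sd == 0 or n == 0:
        return np.zeros((3, n))
    t = np.arange(n) / rate
    out = np.zeros((3, n))
    for axis in range(3):
        for period in (11.0, 29.0):
            phase = rng.uniform(0, 2 * np.pi)
            out[axis] += np.sin(2 * np.pi * t / period + phase)
    return out * (sd / np.sqrt(2))


def synth_activity_segment(
    label: ActivityLabel,
    duration: float,
    rate: float,
    params: ActivityModelParams,
    rng: np.random.Generator,
    *,
    g: float = STANDARD_GRAVITY,
    t_start: float = 0.0,
    n_samples: int | None = None,
) -> np.ndarray:
    """One activity's raw 6 x (duration*rate) signal block.

    Acceleration rows are gravity plus weighted sinusoid harmonics of the
    step frequency; gyroscope rows oscillate around zero.  ``t_start``
    offsets the time axis so stitched segments keep phase continuity.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate)) if n_samples is None else n_samples
    t = t_start + np.arange(n) / rate
    acc = np.tile(g * np.asarray(params.gravity_orientation)[:, None], (1, n))
    gyr = np.zeros((3, n))
    if params.step_frequency > 0:
        for k, w in enumerate(params.harmonic_weights):
            freq = (k + 1) * params.step_frequency
            phase_a = rng.uniform(0, 2 * np.pi, size=3)
            phase_g = rng.uniform(0, 2 * np.pi, size=3)
            osc = np.sin(2 * np.pi * freq * t[None, :] + phase_a[:, None])
            acc += w * np.asarray(params.accel_amplitude)[:, None] * osc
            osc_g = np.sin(2 * np.pi * freq * t[None, :] + phase_g[:, None])
            gyr += w * np.asarray(params.gyro_amplitude)[:, None] * osc_g
    acc += _drift(n, rate, params.drift_sd, rng)
    gyr += _drift(n, rate, params.drift_sd * 0.2, rng)
    if params.noise_sd_accel > 0:
        acc += rng.normal(0, params.noise_sd_accel, size=(3, n))
    if params.noise_sd_gyro > 0:
        gyr += rng.normal(0, params.noise_sd_gyro, size=(3, n))
    return np.vstack([acc, gyr])


CROSSFADE_SECONDS = 0.5  # total width of the linear blend at each boundary


def synth_recording(
    plan: CoursePlan,
    domain: DomainParams,
    rate: float = 50.0,
    participant_id: str = "synthetic",
    seed: int = 0,
) -> Recording:
    """Stitch per-activity segments into one labeled course recording.

    Adjacent segments are blended with a linear cross-fade of
    ``CROSSFADE_SECONDS`` centered on each boundary; label spans match the
    plan intervals exactly.
    """
    rng = np.random.default_rng(seed)
    n_total = int(round(plan.total_duration * rate))
    t = np.arange(n_total) / rate
    h = CROSSFADE_SECONDS / 2.0
    out = np.zeros((6, n_total))
    edges = np.cumsum([0.0] + [d for _, d in plan.segments])
    for i, (lab, dur) in enumerate(plan.segments):
        s, e = edges[i], edges[i + 1]
        lo = s - h if i > 0 else 0.0
        hi = e + h if i < len(plan.segments) - 1 else plan.total_duration
        idx = np.nonzero((t >= lo - 1e-12) & (t < hi - 1e-12))[0]
        if idx.size == 0:
            continue
        params = domain.activities[lab]
        seg = synth_activity_segment(
            lab,
            duration=idx.size / rate,
            rate=rate,
            params=params,
            rng=rng,
            g=domain.g,
            t_start=float(t[idx[0]]),
            n_samples=idx.size,
        )
        w = np.ones(idx.size)
        ts = t[idx]
        if i > 0:
            w = np.minimum(w, (ts - (s - h)) / (2 * h))
        if i < len(plan.segments) - 1:
            w = np.minimum(w, ((e + h) - ts) / (2 * h))
        out[:, idx] += np.clip(w, 0.0, 1.0) * seg
    out = np.vstack([domain.rotation @ out[:3], domain.rotation @ out[3:]])
    return Recording(
        participant_id=participant_id,
        sampling_rate=rate,
        channels=DEFAULT_CHANNELS,
        samples=out,
        t0=0.0,
        label_spans=plan.spans(),
    )


def _jitter_params(
    p: ActivityModelParams, rng: np.random.Generator
) -> ActivityModelParams:
    """Small per-participant perturbation of cadence and energy."""
    freq = p.step_frequency
    if freq > 0:
        freq = max(0.5, freq + rng.normal(0, 0.08))
    scale = float(np.exp(rng.normal(0, 0.08)))
    wobble = Rotation.from_rotvec(rng.normal(0, 0.05, size=3)).as_matrix()
    grav = _unit(wobble @ np.asarray(p.gravity_orientation))
    return replace(
        p,
        step_frequency=freq,
        gravity_orientation=grav,
        accel_amplitude=tuple(a * scale for a in p.accel_amplitude),
        gyro_amplitude=tuple(a * scale for a in p.gyro_amplitude),
    )


def participant_domain(
    domain: DomainParams, participant_seed: int
) -> DomainParams:
    rng = np.random.default_rng(participant_seed)
    return replace(
        domain,
        activities={lab: _jitter_params(p, rng) for lab, p in domain.activities.items()},
    )


def synth_recordings(
    n_participants: int,
    domain: DomainParams | None = None,
    plan: CoursePlan | None = None,
    rate: float = 50.0,
    seed: int = 0,
) -> list[Recording]:
    """Per-participant course recordings with seeded parameter jitter."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    domain = domain or default_domain()
    plan = plan or default_course_plan()
    root = np.random.default_rng(seed)
    recs = []
    for i in range(n_participants):
        pseed = int(root.integers(0, 2**63 - 1))
        pdomain = participant_domain(domain, pseed)
        recs.append(
            synth_recording(
                plan,
                pdomain,
                rate=rate,
                participant_id=f"p{i:03d}",
                seed=int(root.integers(0, 2**63 - 1)),
            )
        )
    return recs


def synth_dataset(
    n_participants: int,
    domain: DomainParams | None = None,
    plan: CoursePlan | None = None,
    rate: float = 50.0,
    seed: int = 0,
    window_len: int = DEFAULT_WINDOW_LEN,
    step: int = DEFAULT_STEP,
    label_policy: str = "pure",
) -> Dataset:
    """Generate, label, and window a synthetic multi-participant dataset."""
    recs = synth_recordings(n_participants, domain, plan, rate, seed)
    windows = []
    for rec in recs:
        windows.extend(segment_windows(rec, window_len, step, label_policy))
    return Dataset(windows, DEFAULT_CHANNELS)


def shifted_domain(
    base: DomainParams,
    severity: float,
    seed: int = 0,
    *,
    max_angle_deg: float = 90.0,
) -> DomainParams:
    """A domain displaced from ``base`` proportionally to ``severity`` in [0, 1].

    The wearing orientation rotates by severity·max_angle about a seeded
    random axis, amplitudes scale up, and cadences shift — emulating a
    different population recorded with a different phone placement.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if severity == 0.0:
        return base
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(max_angle_deg) * severity
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    amp_scale = 1.0 + 0.5 * severity
    freq_shift = 0.5 * severity
    new_acts = {}
    for lab, p in base.activities.items():
        freq = p.step_frequency + (freq_shift if p.step_frequency > 0 else 0.0)
        new_acts[lab] = replace(
            p,
            step_frequency=freq,
            accel_amplitude=tuple(a * amp_scale for a in p.accel_amplitude),
            gyro_amplitude=tuple(a * amp_scale for a in p.gyro_amplitude),
        )
    return replace(
        base,
        activities=new_acts,
        orientation=tuple(map(tuple, R @ base.rotation)),
    )
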