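"""Synthetic two-sensor inertial sessions with the measurement protocol's structure.

No public recordings exist for the scripted sessions, so every stage is
exercised on generated data that reproduces what the features consume:

- sensor readings scatter as Gaussians around their true value;
- each activity holds a characteristic chest/thigh orientation (gravity
  vector tilted from the calibrated vertical);
- dynamic motions add (a) a nonzero mean thigh angular velocity with a
  sinusoidal gait sway on top, (b) a forward acceleration offset with a
  slow stride-to-stride modulation (so consecutive window means differ and
  the gradient features respond), and (c) wide-band acceleration noise
  whose σ separates walk from run;
- a flexion exercise steps the arm sensors' gravity direction through
  5-s dwell plateaus.

Every generator is bit-reproducible for a fixed seed.  Windows overlapping
the between-activity transition gaps are labeled ``transition`` and are
excluded from recognition scoring, mirroring the measurement protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from motionfis.imu_signals import SensorStream, stream_from_arrays

TRANSITION = "transition"

#: Frequency (Hz) of the slow stride-to-stride modulation that makes
#: consecutive window means differ (drives the gradient features).
_MOD_FREQ_HZ = 0.5


@dataclass(frozen=True)
class MotionProfile:
    """Signal parameters for one activity.

    Angles in degrees, accelerations in g, angular velocities in °/s.
    Static postures have zero sway/offset terms.
    """

    chest_tilt_deg: float
    thigh_tilt_deg: float
    chest_acc_noise_g: float
    thigh_acc_noise_g: float
    gyro_noise_dps: float
    thigh_omega_mean_dps: float = 0.0  # mean thigh angular velocity (1-axis)
    thigh_sway_rms_dps: float = 0.0  # RMS of the sinusoidal gait sway
    sway_freq_hz: float = 0.0
    chest_omega_mod_dps: float = 0.0  # slow chest rotation modulation amplitude
    thigh_acc_offset_g: float = 0.0  # mean forward acceleration offset
    thigh_acc_mod_g: float = 0.0  # slow forward-acceleration modulation amplitude


#: Default per-activity profiles.  Static tilts follow the posture geometry
#: (thigh roughly horizontal for sit and lie, chest horizontal for lie);
#: dynamic parameters are anchored to the published cues (walk/run thigh
#: sway RMS below/above 25 °/s, chest acceleration σ below/above ~0.1 g)
#: and sit inside the membership plateaus their rules must trigger.
DEFAULT_PROFILES: dict[str, MotionProfile] = {
    "stand": MotionProfile(0.0, 0.0, 0.005, 0.005, 0.5),
    "sit": MotionProfile(5.0, 85.0, 0.005, 0.005, 0.5),
    "lie": MotionProfile(88.0, 75.0, 0.005, 0.005, 0.5),
    "walk": MotionProfile(
        2.0, 10.0, 0.15, 0.15, 2.0,
        thigh_omega_mean_dps=80.0, thigh_sway_rms_dps=15.0, sway_freq_hz=1.8,
        chest_omega_mod_dps=40.0, thigh_acc_offset_g=0.18, thigh_acc_mod_g=0.06,
    ),
    "run": MotionProfile(
        2.0, 10.0, 0.4, 0.5, 4.0,
        thigh_omega_mean_dps=150.0, thigh_sway_rms_dps=45.0, sway_freq_hz=2.8,
        chest_omega_mod_dps=60.0, thigh_acc_offset_g=0.75, thigh_acc_mod_g=0.25,
    ),
}


@dataclass(frozen=True)
class ActivityScript:
    """Ordered (activity, duration s) segments with inter-segment gaps."""

    segments: tuple[tuple[str, float], ...]
    gap_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script needs at least one segment")
        for act, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment {act!r} has non-positive duration")
        if self.gap_s < 0:
            raise ValueError("gap must be non-negative")

    def intervals(self) -> list[tuple[str, float, float]]:
        """(activity, start s, end s) for every segment, gaps between."""
        out = []
        t = 0.0
        for i, (act, dur) in enumerate(self.segments):
            if i > 0:
                t += self.gap_s
            out.append((act, t, t + dur))
            t += dur
        return out

    @property
    def total_duration(self) -> float:
        return self.intervals()[-1][2]


def default_session_script() -> ActivityScript:
    """The scripted measurement session: an opening stand segment (the
    calibration posture) followed by sit 10 s, stand 10 s, run 6 s,
    walk 10 s, lie 10 s."""
    return ActivityScript(
        segments=(
            ("stand", 10.0),
            ("sit", 10.0),
            ("stand", 10.0),
            ("run", 6.0),
            ("walk", 10.0),
            ("lie", 10.0),
        )
    )


@dataclass
class SimulatedSession:
    """Generated chest/thigh streams plus the ground-truth script."""

    chest: SensorStream
    thigh: SensorStream
    script: ActivityScript
    rate: float
    seed: int | None

    def window_labels(self, width_s: float = 1.0) -> list[str]:
        """Ground-truth activity per window; ``transition`` flags windows
        touched by a change of action.  A window is flagged when it is not
        fully inside one segment, or when its predecessor window lies in a
        different segment (the gradient features of the first window after
        a change still see the change).  Trailing partial windows are
        excluded, matching the windowing rule."""
        n_per = int(round(width_s * self.rate))
        n_windows = len(self.chest) // n_per
        intervals = self.script.intervals()
        eps = 1e-9

        def segment_of(k: int) -> str:
            w0, w1 = k * width_s, (k + 1) * width_s
            for act, s0, s1 in intervals:
                if w0 >= s0 - eps and w1 <= s1 + eps:
                    return act
            return TRANSITION

        labels = []
        for k in range(n_windows):
            label = segment_of(k)
            if k > 0 and label != TRANSITION and segment_of(k - 1) != label:
                label = TRANSITION
            labels.append(label)
        return labels


def _tilted_gravity(tilt_deg: float) -> np.ndarray:
    """Gravity in local axes for a tilt in the 1-3 plane (1-axis vertical
    at calibration, |g| = 1 g)."""
    th = np.radians(tilt_deg)
    return np.array([np.cos(th), 0.0, np.sin(th)])


def _sample_tilts(script: ActivityScript, profiles, t: np.ndarray, which: str) -> np.ndarray:
    """Per-sample tilt angle, linearly interpolated across gaps."""
    attr = f"{which}_tilt_deg"
    intervals = script.intervals()
    knots_t: list[float] = []
    knots_a: list[float] = []
    for act, s0, s1 in intervals:
        a = getattr(profiles[act], attr)
        knots_t += [s0, s1]
        knots_a += [a, a]
    return np.interp(t, knots_t, knots_a)


def simulate_session(
    script: ActivityScript | None = None,
    profiles: dict[str, MotionProfile] | None = None,
    rate: float = 20.0,
    seed: int | None = None,
) -> SimulatedSession:
    """Generate one scripted chest+thigh session.

    Per sample: gravity tilted per the active profile, Gaussian sensor
    noise on every axis, and for dynamic segments the thigh angular-velocity
    sway plus forward-acceleration offset/modulation described in the module
    docstring.
    """
    script = script or default_session_script()
    profiles = profiles or DEFAULT_PROFILES
    for act, _ in script.segments:
        if act not in profiles:
            raise ValueError(f"no motion profile for activity {act!r}")
    rng = np.random.default_rng(seed)
    n = int(round(script.total_duration * rate))
    t = np.arange(n) / rate

    chest_acc = np.empty((n, 3))
    thigh_acc = np.empty((n, 3))
    chest_gyro = np.zeros((n, 3))
    thigh_gyro = np.zeros((n, 3))

    # orientation (gravity) per sample, interpolated through gaps
    for i, th in enumerate(_sample_tilts(script, profiles, t, "chest")):
        chest_acc[i] = _tilted_gravity(th)
    for i, th in enumerate(_sample_tilts(script, profiles, t, "thigh")):
        thigh_acc[i] = _tilted_gravity(th)

    # per-sample noise levels and dynamic terms, segment by segment
    intervals = script.intervals()

    def active_profile(ti: float) -> MotionProfile:
        for act, s0, s1 in intervals:
            if s0 <= ti < s1:
                return profiles[act]
        return profiles["stand"]  # gap: quiet static noise

    mod = np.sin(2 * np.pi * _MOD_FREQ_HZ * t)
    for i, ti in enumerate(t):
        p = active_profile(ti)
        sway = p.thigh_sway_rms_dps * np.sqrt(2.0) * np.sin(2 * np.pi * p.sway_freq_hz * ti)
        thigh_gyro[i, 0] += p.thigh_omega_mean_dps + sway
        chest_gyro[i, 0] += p.chest_omega_mod_dps * mod[i]
        thigh_acc[i, 0] += p.thigh_acc_offset_g + p.thigh_acc_mod_g * mod[i]
        chest_acc[i] += rng.normal(0.0, p.chest_acc_noise_g, 3)
        thigh_acc[i] += rng.normal(0.0, p.thigh_acc_noise_g, 3)
        chest_gyro[i] += rng.normal(0.0, p.gyro_noise_dps, 3)
        thigh_gyro[i] += rng.normal(0.0, p.gyro_noise_dps, 3)

    np.clip(chest_acc, -10.0, 10.0, out=chest_acc)
    np.clip(thigh_acc, -10.0, 10.0, out=thigh_acc)
    np.clip(chest_gyro, -1000.0, 1000.0, out=chest_gyro)
    np.clip(thigh_gyro, -1000.0, 1000.0, out=thigh_gyro)

    chest = stream_from_arrays("chest_A", rate, t, chest_acc, chest_gyro)
    thigh = stream_from_arrays("thigh_B", rate, t, thigh_acc, thigh_gyro)
    return SimulatedSession(chest=chest, thigh=thigh, script=script, rate=rate, seed=seed)


@dataclass(frozen=True)
class FlexionScript:
    """One flexion exercise: plateau targets held ``step_dwell_s`` each.

    ``flex_elbow`` repeats one target angle (several repetitions);
    ``raise_arm`` climbs a staircase of targets.  The emitted streams open
    with one dwell at 0° for calibration.
    """

    action: str  # flex_elbow | raise_arm
    plateaus: tuple[float, ...]
    step_dwell_s: float = 5.0
    angle_error_deg: float = 0.0  # per-step Gaussian error on the target

    def __post_init__(self) -> None:
        if self.action not in ("flex_elbow", "raise_arm"):
            raise ValueError(f"unknown flexion action {self.action!r}")
        if not self.plateaus:
            raise ValueError("flexion script needs at least one plateau")
        if self.step_dwell_s <= 0:
            raise ValueError("dwell must be positive")


def simulate_flexion(
    script: FlexionScript,
    rate: float = 20.0,
    seed: int | None = None,
    acc_noise_g: float = 0.005,
) -> tuple[SensorStream, SensorStream]:
    """Generate wrist (C) and upper-arm (D) streams for a flexion exercise.

    The gravity direction of both sensors steps through 0° then each
    plateau (held ``step_dwell_s`` each), with a per-step angle error drawn
    once per step and per-sample Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    dwell = script.step_dwell_s
    angles = [0.0] + [
        p + (rng.normal(0.0, script.angle_error_deg) if script.angle_error_deg > 0 else 0.0)
        for p in script.plateaus
    ]
    n_per = int(round(dwell * rate))
    n = n_per * len(angles)
    t = np.arange(n) / rate
    acc_w = np.empty((n, 3))
    acc_u = np.empty((n, 3))
    gyro = rng.normal(0.0, 0.5, (n, 3))
    for s, ang in enumerate(angles):
        g = _tilted_gravity(ang)
        acc_w[s * n_per : (s + 1) * n_per] = g
        acc_u[s * n_per : (s + 1) * n_per] = g
    acc_w += rng.normal(0.0, acc_noise_g, (n, 3))
    acc_u += rng.normal(0.0, acc_noise_g, (n, 3))
    wrist = stream_from_arrays("wrist_C", rate, t, acc_w, gyro)
    upper = stream_from_arrays("upper_arm_D", rate, t, acc_u, rng.normal(0.0, 0.5, (n, 3)))
    return wrist, upper


@dataclass(frozen=True)
class TrainingClassParams:
    """Gaussian parameters of one class's (σ_gBx, σ_gBy, σ_gBz) triple."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]


#: Default class parameters for the walk/run training-set generator: the
#: per-axis thigh acceleration deviations of walking sit well below those
#: of running, with class means separated by several pooled σ.
DEFAULT_CLASS_PARAMS: dict[str, TrainingClassParams] = {
    "walk": TrainingClassParams(mean=(0.35, 0.30, 0.25), sd=(0.08, 0.08, 0.08)),
    "run": TrainingClassParams(mean=(1.10, 0.95, 0.85), sd=(0.12, 0.12, 0.12)),
}


def make_training_set(
    n_records: int = 187,
    class_params: dict[str, TrainingClassParams] | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Labeled walk/run feature records for motion-index training.

    Returns (X, labels, targets): an (n, 3) matrix of σ_gB triples drawn
    per class, the class labels, and target motion indexes drawn uniformly
    within each label's band.  The default size of 187 records matches the
    reference training-set size (change-of-motion records excluded).
    """
    if n_records < 1:
        raise ValueError("n_records must be ≥ 1")
    params = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(seed)
    classes = sorted(params)
    n_per = [n_records // len(classes)] * len(classes)
    n_per[-1] += n_records - sum(n_per)
    X_parts, labels = [], []
    for cls, k in zip(classes, n_per):
        p = params[cls]
        draws = rng.normal(p.mean, p.sd, size=(k, 3))
        X_parts.append(np.clip(draws, 1e-3, 2.0))
        labels += [cls] * k
    X = np.vstack(X_parts)
    from motionfis.anfis import label_training_data

    targets = label_training_data(labels, rng)
    return X, labels, targets
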