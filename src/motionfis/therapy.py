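"""Flexion-exercise recognition and compliance scoring.

Two prescribed upper-limb exercises are assessed from wrist (C) and
upper-arm (D) sensors: (a) flex the elbow to ~135° (here assessed at the
published per-repetition target band) and (b) raise the arm through four
45° steps.  Each step dwells 5 s; the recognized step angle is the median
tilt over the dwell's windows, rounded to integer degrees, and a step
passes when its angle falls inside the prescribed threshold interval
(bounds inclusive at both ends).  Results feed pipe-delimited motion
packets ("n|time|motion_1|motion_2", −1 = motion absent) and a structured
session report with per-motion pass/fail labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from motionfis.imu_signals import (
    CalibrationBaseline,
    SensorStream,
    StreamValidationError,
    calibrate,
    window_means,
)
from motionfis.features import tilt_angle

#: Published step thresholds for the staircase arm raise; the elbow flexion
#: uses the first interval only.
DEFAULT_THRESHOLDS: tuple[tuple[float, float], ...] = (
    (40.0, 45.0),
    (85.0, 90.0),
    (130.0, 135.0),
    (175.0, 180.0),
)


@dataclass(frozen=True)
class FlexionThresholds:
    """Ordered, non-overlapping inclusive angle intervals (degrees)."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) reversed")
            if lo <= prev_hi:
                raise ValueError("threshold intervals must be increasing and disjoint")
            prev_hi = hi

    def __len__(self) -> int:
        return len(self.intervals)


def elbow_thresholds() -> FlexionThresholds:
    """Action (a): one target band applied to every repetition."""
    return FlexionThresholds(intervals=DEFAULT_THRESHOLDS[:1])


def arm_raise_thresholds() -> FlexionThresholds:
    """Action (b): the four-step staircase bands."""
    return FlexionThresholds(intervals=DEFAULT_THRESHOLDS)


@dataclass(frozen=True)
class FlexionResult:
    action: str
    angles: tuple[int, ...]
    pass_flags: tuple[bool, ...]
    required: int

    @property
    def passes(self) -> int:
        return sum(self.pass_flags)

    def as_dict(self) -> dict:
        return {
            "action": self.action,
            "angles": list(self.angles),
            "pass_flags": list(self.pass_flags),
            "passes": self.passes,
            "required": self.required,
        }


def recognize_step_angles(
    wrist: SensorStream,
    upper_arm: SensorStream,
    dwell_s: float = 5.0,
    width_s: float = 1.0,
) -> list[tuple[int, int]]:
    """Recognized (θ_C, θ_D) per dwell step, integer degrees.

    The first dwell is the 0° calibration posture; each later dwell yields
    the median per-window tilt of both sensors relative to that baseline.
    """
    n_win_per_dwell = int(round(dwell_s / width_s))
    if n_win_per_dwell < 1:
        raise ValueError("dwell shorter than one window")
    wins_w = window_means(wrist, width_s)
    wins_u = window_means(upper_arm, width_s)
    if len(wins_w) < 2 * n_win_per_dwell:
        raise StreamValidationError("stream shorter than calibration dwell + one step")
    cal_w = calibrate(wrist, n_init=n_win_per_dwell, width_s=width_s)
    cal_u = calibrate(upper_arm, n_init=n_win_per_dwell, width_s=width_s)
    n_steps = min(len(wins_w), len(wins_u)) // n_win_per_dwell - 1
    out: list[tuple[int, int]] = []
    for s in range(1, n_steps + 1):
        sl = slice(s * n_win_per_dwell, (s + 1) * n_win_per_dwell)
        th_c = np.median([tilt_angle(w.mean_acc, cal_w.g0) for w in wins_w[sl]])
        th_d = np.median([tilt_angle(w.mean_acc, cal_u.g0) for w in wins_u[sl]])
        out.append((int(round(th_c)), int(round(th_d))))
    return out


def assess(
    angles: Sequence[float],
    thresholds: FlexionThresholds,
    mode: str = "per_step",
    action: str = "flexion",
) -> FlexionResult:
    """Pass/fail each recognized step angle against the thresholds.

    With a single interval, every angle is checked against it (repetition
    exercises).  Otherwise ``per_step`` matches the i-th angle to the i-th
    interval (staircase exercises) and ``any_interval`` passes an angle
    inside any interval.  Bounds are inclusive.
    """
    if not angles:
        raise ValueError("no recognized angles to assess")
    if mode not in ("per_step", "any_interval"):
        raise ValueError(f"unknown mode {mode!r}")
    flags: list[bool] = []
    if len(thresholds) == 1:
        lo, hi = thresholds.intervals[0]
        flags = [lo <= a <= hi for a in angles]
        required = len(angles)
    elif mode == "any_interval":
        flags = [any(lo <= a <= hi for lo, hi in thresholds.intervals) for a in angles]
        required = len(angles)
    else:
        required = len(thresholds)
        for i, (lo, hi) in enumerate(thresholds.intervals):
            flags.append(i < len(angles) and lo <= angles[i] <= hi)
    return FlexionResult(
        action=action,
        angles=tuple(int(round(a)) for a in angles),
        pass_flags=tuple(flags),
        required=required,
    )


@dataclass(frozen=True)
class Packet:
    """One motion record: serial, timestamp, elbow-flex angle, arm-raise angle.

    −1 (stored as None) marks "no motion of this type".
    """

    n: int
    time: str
    motion_1: int | None
    motion_2: int | None


def format_packet(p: Packet) -> str:
    m1 = -1 if p.motion_1 is None else p.motion_1
    m2 = -1 if p.motion_2 is None else p.motion_2
    return f"{p.n}|{p.time}|{m1}|{m2}"


def parse_packet(text: str) -> Packet:
    """Parse "n|time|motion_1|motion_2"; accepts the typographic minus."""
    parts = text.strip().replace("−", "-").split("|")
    if len(parts) != 4:
        raise ValueError(f"packet needs 4 pipe-delimited fields, got {len(parts)}")
    try:
        n = int(parts[0])
        m1 = int(parts[2])
        m2 = int(parts[3])
    except ValueError as exc:
        raise ValueError(f"non-numeric packet field: {exc}") from None
    return Packet(
        n=n,
        time=parts[1],
        motion_1=None if m1 == -1 else m1,
        motion_2=None if m2 == -1 else m2,
    )


def session_report(results: Sequence[FlexionResult], period: str = "") -> dict:
    """Machine-readable compliance report over a set of exercise results."""
    motions = []
    for r in results:
        motions.append(
            {
                **r.as_dict(),
                "status": "pass" if r.passes == r.required else "fail",
                "pass_rate": f"{r.passes}/{r.required}",
            }
        )
    total_pass = sum(r.passes for r in results)
    total_req = sum(r.required for r in results)
    return {
        "period": period,
        "motions": motions,
        "total_passes": total_pass,
        "total_required": total_req,
        "overall_rate": (total_pass / total_req) if total_req else None,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
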