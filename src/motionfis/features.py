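"""Movement features computed from windowed two-sensor streams.

All features are defined relative to the calibration baseline taken in the
opening stand posture:

- tilt angles θ_A, θ_B: angle between the current window-mean gravity vector
  and the initial one, from the normalized inner product (degrees, [0, 180]);
  θ_AB is the angle between the two sensors' gravity vectors
- relative vectors g_R = g − g0, ω_R = ω − ω0 (motion on top of gravity /
  gyro bias)
- per-axis within-window standard deviations σ (population form, divisor n)
- difference rates ν = |V − V0|² / |V0|² (dimensionless)
- gradients γ = (m_i − m_{i−1}) / Δt of consecutive window means
  (undefined on the first window, emitted as NaN)

Two five-feature projections feed the fuzzy classifiers: SET-1 uses
{θ_A, θ_B, ω_BRx, g_BRx, σ_gBx}, SET-2 uses {θ_A, θ_B, γ_ωAx, γ_gBx, σ_gAx}.
The "x" component is the local 1-axis (vertical at calibration); dynamic
features enter the fuzzy systems as absolute values, since every membership
support starts at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from motionfis.imu_signals import CalibrationBaseline, WindowSummary

logger = logging.getLogger(__name__)

SET1_NAMES = ("theta_A", "theta_B", "omega_BRx", "g_BRx", "sigma_gBx")
SET2_NAMES = ("theta_A", "theta_B", "gamma_wAx", "gamma_gBx", "sigma_gAx")


class DegenerateVectorError(ValueError):
    """A feature formula received a zero-norm vector where a direction is needed."""


def relative_vector(v: np.ndarray, v0: np.ndarray) -> np.ndarray:
    """Componentwise difference of a measurement from its initial value."""
    return np.asarray(v, dtype=float) - np.asarray(v0, dtype=float)


def tilt_angle(gi: np.ndarray, g0: np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between a gravity vector and its baseline.

    The cosine is clamped to [−1, 1] before arccos to absorb rounding.
    """
    gi = np.asarray(gi, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    ni, n0 = np.linalg.norm(gi), np.linalg.norm(g0)
    if ni == 0.0 or n0 == 0.0:
        raise DegenerateVectorError("tilt angle undefined for a zero-norm vector")
    c = float(np.dot(gi, g0) / (ni * n0))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def tilt_between(gA: np.ndarray, gB: np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between the two sensors' gravity vectors."""
    return tilt_angle(gA, gB)


def window_std(values: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Population standard deviation (divisor n) of the within-window samples.

    Accepts a 1-D sequence (returns a scalar) or an (n, 3) matrix (returns
    the per-axis 3-vector).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("standard deviation of an empty sequence is undefined")
    out = arr.std(axis=0, ddof=0)
    return float(out) if np.ndim(out) == 0 else out


def diff_rate(Vi: np.ndarray, V0: np.ndarray) -> float:
    """Normalized squared difference |Vi − V0|² / |V0|² (dimensionless)."""
    Vi = np.asarray(Vi, dtype=float)
    V0 = np.asarray(V0, dtype=float)
    n0sq = float(np.dot(V0, V0))
    if n0sq == 0.0:
        raise DegenerateVectorError("difference rate undefined for zero baseline")
    d = Vi - V0
    return float(np.dot(d, d) / n0sq)


def gradient(xi: float, xprev: float, dt: float) -> float:
    """Finite-difference gradient (xi − xprev)/dt of consecutive window means."""
    if dt <= 0:
        raise ValueError("gradient time step must be positive")
    return (xi - xprev) / dt


@dataclass(frozen=True)
class FeatureFrame:
    """All movement features for one window (chest = A, thigh = B).

    Gradients on the first window of a session are NaN (no predecessor).
    Angles in degrees, accelerations in g, angular velocities in °/s,
    gradients in g/s and °/s².
    """

    window_index: int
    t_mid: float
    theta_A: float
    theta_B: float
    theta_AB: float
    gAR: np.ndarray
    gBR: np.ndarray
    omegaAR: np.ndarray
    omegaBR: np.ndarray
    sigma_gA: np.ndarray
    sigma_gB: np.ndarray
    sigma_wA: np.ndarray
    sigma_wB: np.ndarray
    nu_gAR: float
    nu_gBR: float
    gamma_gA: np.ndarray
    gamma_gB: np.ndarray
    gamma_wA: np.ndarray
    gamma_wB: np.ndarray

    @property
    def has_gradients(self) -> bool:
        return not np.any(np.isnan(self.gamma_gA))


def extract_features(
    chest: Sequence[WindowSummary],
    thigh: Sequence[WindowSummary],
    cal_chest: CalibrationBaseline,
    cal_thigh: CalibrationBaseline,
    dt: float = 1.0,
) -> list[FeatureFrame]:
    """Compute one FeatureFrame per window from paired sensor windows.

    ``dt`` is the window width in seconds (the gradient time step).
    """
    if len(chest) != len(thigh):
        raise ValueError(
            f"window counts differ: chest {len(chest)} vs thigh {len(thigh)}"
        )
    frames: list[FeatureFrame] = []
    nan3 = np.full(3, np.nan)
    for i, (wa, wb) in enumerate(zip(chest, thigh)):
        if i == 0:
            g_gA = g_gB = g_wA = g_wB = nan3
        else:
            pa, pb = chest[i - 1], thigh[i - 1]
            g_gA = (wa.mean_acc - pa.mean_acc) / dt
            g_gB = (wb.mean_acc - pb.mean_acc) / dt
            g_wA = (wa.mean_gyro - pa.mean_gyro) / dt
            g_wB = (wb.mean_gyro - pb.mean_gyro) / dt
        frames.append(
            FeatureFrame(
                window_index=wa.window_index,
                t_mid=wa.t_mid,
                theta_A=tilt_angle(wa.mean_acc, cal_chest.g0),
                theta_B=tilt_angle(wb.mean_acc, cal_thigh.g0),
                theta_AB=tilt_between(wa.mean_acc, wb.mean_acc),
                gAR=relative_vector(wa.mean_acc, cal_chest.g0),
                gBR=relative_vector(wb.mean_acc, cal_thigh.g0),
                omegaAR=relative_vector(wa.mean_gyro, cal_chest.omega0),
                omegaBR=relative_vector(wb.mean_gyro, cal_thigh.omega0),
                sigma_gA=window_std(wa.raw_acc),
                sigma_gB=window_std(wb.raw_acc),
                sigma_wA=window_std(wa.raw_gyro),
                sigma_wB=window_std(wb.raw_gyro),
                nu_gAR=diff_rate(wa.mean_acc, cal_chest.g0),
                nu_gBR=diff_rate(wb.mean_acc, cal_thigh.g0),
                gamma_gA=g_gA,
                gamma_gB=g_gB,
                gamma_wA=g_wA,
                gamma_wB=g_wB,
            )
        )
    return frames


def to_set1(frame: FeatureFrame) -> np.ndarray:
    """Project a frame onto {θ_A, θ_B, |ω_BRx|, |g_BRx|, σ_gBx}."""
    return np.array(
        [
            frame.theta_A,
            frame.theta_B,
            abs(frame.omegaBR[0]),
            abs(frame.gBR[0]),
            frame.sigma_gB[0],
        ]
    )


def to_set2(frame: FeatureFrame) -> np.ndarray:
    """Project a frame onto {θ_A, θ_B, |γ_ωAx|, |γ_gBx|, σ_gAx}.

    Raises ValueError on the first window of a session, whose gradients
    are undefined; use :func:`feature_matrix` to skip such frames.
    """
    if not frame.has_gradients:
        raise ValueError(
            f"window {frame.window_index}: gradients undefined (first window)"
        )
    return np.array(
        [
            frame.theta_A,
            frame.theta_B,
            abs(frame.gamma_wA[0]),
            abs(frame.gamma_gB[0]),
            frame.sigma_gA[0],
        ]
    )


def feature_matrix(
    frames: Sequence[FeatureFrame], feature_set: int
) -> tuple[np.ndarray, list[int]]:
    """Stack frames into an (n, 5) matrix for the chosen feature set.

    Frames without gradients (the session's first window) are skipped for
    SET-2 with a logged notice.  Returns the matrix and the window indices
    of the retained frames.
    """
    if feature_set not in (1, 2):
        raise ValueError("feature_set must be 1 or 2")
    rows, kept = [], []
    for f in frames:
        if feature_set == 1:
            rows.append(to_set1(f))
        else:
            if not f.has_gradients:
                logger.info(
                    "skipping window %d: gradients undefined", f.window_index
                )
                continue
            rows.append(to_set2(f))
        kept.append(f.window_index)
    return np.array(rows).reshape(-1, 5), kept


def frames_to_dataframe(frames: Sequence[FeatureFrame]) -> pd.DataFrame:
    """Flatten frames to a table (one row per window, fixed column names)."""
    recs = []
    for f in frames:
        rec = {
            "window_index": f.window_index,
            "t_mid": f.t_mid,
            "theta_A": f.theta_A,
            "theta_B": f.theta_B,
            "theta_AB": f.theta_AB,
            "nu_gAR": f.nu_gAR,
            "nu_gBR": f.nu_gBR,
        }
        for name in (
            "gAR", "gBR", "omegaAR", "omegaBR",
            "sigma_gA", "sigma_gB", "sigma_wA", "sigma_wB",
            "gamma_gA", "gamma_gB", "gamma_wA", "gamma_wB",
        ):
            vec = getattr(f, name)
            for ax, comp in zip("xyz", vec):
                rec[f"{name}{ax}"] = comp
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
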