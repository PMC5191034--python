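"""Containers and I/O for two-sensor inertial streams.

A session is measured by two 6-axis sensors (3-axis acceleration in g,
3-axis angular velocity in °/s).  Samples are averaged over fixed
non-overlapping windows (1 s by default) and the session opens with a
"stand" segment whose window means define the calibration baseline
(initial gravity and angular-velocity vectors) that all relative features
refer to.

Axis convention: sensor axes are local 1/2/3; at calibration the local
1-axis of both sensors points vertically (along gravity), so features
subscripted "x" use the local-1 component throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PLACEMENTS = ("chest_A", "thigh_B", "wrist_C", "upper_arm_D")

ACC_RANGE_G = 10.0  # device measurement range, ±g
GYRO_RANGE_DPS = 1000.0  # device measurement range, ±°/s

_COLUMNS = ("t", "a1", "a2", "a3", "w1", "w2", "w3")
_TIME_TOL = 1e-6  # uniform-spacing tolerance, s


class StreamValidationError(ValueError):
    """Raised when a stream violates its structural invariants."""


class StreamParseError(ValueError):
    """Raised when a stream file cannot be parsed; names the bad line."""


@dataclass(frozen=True)
class ImuSample:
    """One 6-axis reading: time (s), acceleration (g), angular velocity (°/s)."""

    t: float
    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "acc", np.asarray(self.acc, dtype=float))
        object.__setattr__(self, "gyro", np.asarray(self.gyro, dtype=float))
        if self.acc.shape != (3,) or self.gyro.shape != (3,):
            raise StreamValidationError("acc and gyro must be 3-vectors")
        if np.any(np.abs(self.acc) > ACC_RANGE_G):
            raise StreamValidationError(
                f"acceleration out of device range ±{ACC_RANGE_G} g: {self.acc}"
            )
        if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS):
            raise StreamValidationError(
                f"angular velocity out of device range ±{GYRO_RANGE_DPS} °/s: {self.gyro}"
            )


@dataclass
class SensorStream:
    """Time-ordered 6-axis samples from one sensor placement."""

    placement: str
    rate: float
    samples: list[ImuSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise StreamValidationError(
                f"unknown placement {self.placement!r}; expected one of {PLACEMENTS}"
            )
        if self.rate <= 0:
            raise StreamValidationError("sampling rate must be positive")
        t = self.times
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise StreamValidationError(
                    f"timestamps not strictly increasing at sample {i + 1}"
                )
            if np.any(np.abs(dt - 1.0 / self.rate) > _TIME_TOL):
                raise StreamValidationError(
                    f"sample spacing not uniform at rate {self.rate} Hz"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) acceleration matrix in g."""
        return np.array([s.acc for s in self.samples], dtype=float).reshape(-1, 3)

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) angular-velocity matrix in °/s."""
        return np.array([s.gyro for s in self.samples], dtype=float).reshape(-1, 3)

    @property
    def duration(self) -> float:
        if not self.samples:
            return 0.0
        return self.samples[-1].t - self.samples[0].t + 1.0 / self.rate

    def __len__(self) -> int:
        return len(self.samples)


def stream_from_arrays(
    placement: str, rate: float, t: np.ndarray, acc: np.ndarray, gyro: np.ndarray
) -> SensorStream:
    """Assemble a stream from (n,), (n,3), (n,3) arrays."""
    samples = [ImuSample(float(ti), a, w) for ti, a, w in zip(t, acc, gyro)]
    return SensorStream(placement=placement, rate=rate, samples=samples)


@dataclass(frozen=True)
class WindowSummary:
    """Per-window mean 6-axis reading plus the raw member samples.

    The raw samples are retained because the deviation features (per-axis
    standard deviations) are computed within the window, not from the mean.
    """

    window_index: int
    t_mid: float
    mean_acc: np.ndarray
    mean_gyro: np.ndarray
    raw_acc: np.ndarray
    raw_gyro: np.ndarray


@dataclass(frozen=True)
class CalibrationBaseline:
    """Initial gravity / angular-velocity vectors from the opening stand posture."""

    g0: np.ndarray
    omega0: np.ndarray
    n_init: int


def read_stream(path: str | Path, placement: str) -> SensorStream:
    """Read a delimited-text stream file (header t,a1,a2,a3,w1,w2,w3).

    The sampling rate is inferred from the first two timestamps; spacing
    uniformity and monotonicity are validated on construction.
    """
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise StreamParseError(f"{path}: empty file")
    for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise StreamParseError(
                f"{path}:{lineno}: expected 7 comma-separated fields, got {len(parts)}"
            )
        try:
            rows.append(tuple(float(p) for p in parts))
        except ValueError as exc:
            raise StreamParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    if not rows:
        raise StreamParseError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    t = data[:, 0]
    if len(t) > 1:
        rate = 1.0 / float(np.mean(np.diff(t)))
    else:
        rate = 1.0
    return stream_from_arrays(placement, rate, t, data[:, 1:4], data[:, 4:7])


def write_stream(stream: SensorStream, path: str | Path, decimals: int = 9) -> None:
    """Write a stream as comma-delimited text, re-readable losslessly."""
    if not stream.samples:
        raise StreamValidationError("refusing to write an empty stream")
    path = Path(path)
    fmt = f"%.{decimals}g"
    with path.open("w") as fh:
        fh.write(",".join(_COLUMNS) + "\n")
        for s in stream.samples:
            vals = [s.t, *s.acc, *s.gyro]
            fh.write(",".join(fmt % v for v in vals) + "\n")


def window_means(stream: SensorStream, width_s: float = 1.0) -> list[WindowSummary]:
    """Summarize a stream into non-overlapping windows of ``width_s`` seconds.

    Measured samples scatter around their true value (the device histogram
    is Gaussian), so the per-window arithmetic mean is taken as the actual
    measurement.  A trailing partial window is dropped.
    """
    if width_s <= 0:
        raise ValueError("window width must be positive")
    n_per = int(round(width_s * stream.rate))
    if n_per < 1 or len(stream) < n_per:
        raise StreamValidationError(
            f"stream of {len(stream)} samples shorter than one {width_s}-s window"
        )
    t = stream.times
    acc = stream.acc
    gyro = stream.gyro
    n_windows = len(stream) // n_per
    out: list[WindowSummary] = []
    for k in range(n_windows):
        sl = slice(k * n_per, (k + 1) * n_per)
        out.append(
            WindowSummary(
                window_index=k,
                t_mid=float(np.mean(t[sl])),
                mean_acc=acc[sl].mean(axis=0),
                mean_gyro=gyro[sl].mean(axis=0),
                raw_acc=acc[sl].copy(),
                raw_gyro=gyro[sl].copy(),
            )
        )
    return out


def calibrate(
    stream: SensorStream, n_init: int = 3, width_s: float = 1.0
) -> CalibrationBaseline:
    """Derive the initial-posture baseline from the first ``n_init`` windows.

    The session protocol opens with the static stand posture; its window
    means give the initial gravity vector g0 (≈1 g magnitude) and the
    gyroscope bias omega0.
    """
    if n_init < 1:
        raise ValueError("n_init must be ≥ 1")
    windows = window_means(stream, width_s)
    if len(windows) < n_init:
        raise StreamValidationError(
            f"need {n_init} initial windows for calibration, stream has {len(windows)}"
        )
    head = windows[:n_init]
    g0 = np.mean([w.mean_acc for w in head], axis=0)
    omega0 = np.mean([w.mean_gyro for w in head], axis=0)
    return CalibrationBaseline(g0=g0, omega0=omega0, n_init=n_init)
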