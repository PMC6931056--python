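"""Reading, validating and writing ankle-IMU recordings.

The on-disk format is a plain UTF-8 CSV with a mandatory header row::

    time_s,gyro_x,gyro_y,gyro_z,accel_x,accel_y,accel_z

``time_s`` is session-relative seconds (0-based), gyroscope channels are in
deg/s and accelerometer channels in m/s^2.  Recordings are modelled as
uniformly sampled: the reader infers the sample rate from the median
timestamp spacing (unless one is supplied) and rejects files whose spacing
deviates from it by more than 1% — consumer IMUs timestamp on a fixed clock
and anything worse indicates dropped samples.

By convention the sagittal-plane (foot pitch) axis is gyro ``y`` and its
sign is oriented so that the deceleration spike after heel strike is
*negative*; both axis and sign are configurable for mirrored mountings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError, ConfigurationError

CSV_COLUMNS = ["time_s", "gyro_x", "gyro_y", "gyro_z", "accel_x", "accel_y", "accel_z"]

_AXES = {"x": 0, "y": 1, "z": 2}

PathOrStream = Union[str, Path, IO[str]]


@dataclass
class IOConfig:
    """Options controlling CSV ingestion.

    sample_rate
        Override in Hz; when ``None`` the rate is inferred as
        ``1 / median(dt)`` from the time column.
    axis, sign
        Which gyroscope axis carries the sagittal-plane rotation and how it
        is oriented (+1 keeps the recorded sign, -1 mirrors it).
    rel_jitter_tol
        Maximum relative deviation of any timestamp step from the median
        step before the file is rejected as non-uniform.
    """

    sample_rate: float | None = None
    axis: str = "y"
    sign: int = 1
    rel_jitter_tol: float = 0.01


@dataclass
class IMUSeries:
    """A uniformly sampled 6-axis inertial recording.

    ``gyro`` and ``accel`` are ``(n_samples, 3)`` float arrays (deg/s and
    m/s^2).  Timestamps are implicit: ``t_i = t0 + i / sample_rate``.
    """

    sample_rate: float
    gyro: np.ndarray
    accel: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def validate(self) -> "IMUSeries":
        if self.sample_rate <= 0 or not np.isfinite(self.sample_rate):
            raise ValidationError(f"sample_rate must be a positive real, got {self.sample_rate}")
        for name, arr in (("gyro", self.gyro), ("accel", self.accel)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{name} must have shape (n, 3), got {arr.shape}")
        if self.gyro.shape[0] != self.accel.shape[0]:
            raise ValidationError(
                f"gyro and accel lengths differ: {self.gyro.shape[0]} vs {self.accel.shape[0]}"
            )
        if self.n_samples and not (np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValidationError("non-finite values in sensor channels")
        return self


@dataclass
class SagittalTrace:
    """Single-channel sagittal-plane angular velocity (deg/s).

    Negative excursions mark foot deceleration after heel strike.
    """

    sample_rate: float
    av: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.av = np.asarray(self.av, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.av.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


def read_imu_csv(source: PathOrStream, config: IOConfig | None = None) -> IMUSeries:
    """Read an IMU CSV into a validated :class:`IMUSeries`.

    Raises :class:`FormatError` for missing/renamed columns,
    :class:`EmptyInputError` for a header-only file, and
    :class:`ValidationError` for a non-monotonic or non-uniform time base.
    """
    config = config or IOConfig()
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError("CSV has no header row") from exc
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse CSV: {exc}") from exc

    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if len(frame) == 0:
        raise EmptyInputError("CSV contains a header but no data rows")

    values = frame[CSV_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = int(np.argwhere(~np.isfinite(values).all(axis=1))[0, 0]) + 2
        raise ValidationError(f"non-finite value at CSV line {bad}")

    t = values[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        if (dt <= 0).any():
            bad = int(np.argwhere(dt <= 0)[0, 0]) + 2
            raise ValidationError(f"time_s not strictly increasing at CSV line {bad + 1}")
        med = float(np.median(dt))
        if config.sample_rate is not None:
            rate = float(config.sample_rate)
            expected = 1.0 / rate
        else:
            rate = 1.0 / med
            expected = med
        if np.abs(dt - expected).max() > config.rel_jitter_tol * expected:
            raise ValidationError(
                "timestamps deviate from a uniform rate by more than "
                f"{config.rel_jitter_tol:.0%}"
            )
    else:
        if config.sample_rate is None:
            raise ValidationError("cannot infer sample rate from a single row; supply IOConfig.sample_rate")
        rate = float(config.sample_rate)

    series = IMUSeries(sample_rate=rate, gyro=values[:, 1:4], accel=values[:, 4:7], t0=float(t[0]))
    return series.validate()


def write_imu_csv(series: IMUSeries, sink: PathOrStream) -> None:
    """Write ``series`` in the exact dialect :func:`read_imu_csv` accepts.

    Floats are written with shortest-round-trip repr, so read(write(s))
    reproduces the sensor values exactly.
    """
    series.validate()
    frame = pd.DataFrame(
        np.column_stack([series.times, series.gyro, series.accel]) if series.n_samples
        else np.empty((0, 7)),
        columns=CSV_COLUMNS,
    )
    frame.to_csv(sink, index=False)


def extract_sagittal(series: IMUSeries, axis: str = "y", sign: int = 1) -> SagittalTrace:
    """Select the sagittal-plane gyroscope channel.

    ``sign=-1`` mirrors the channel for sensors mounted on the opposite
    face, keeping the convention that post-heel-strike deceleration is
    negative.
    """
    if axis not in _AXES:
        raise ConfigurationError(f"unknown gyroscope axis {axis!r}; expected one of x, y, z")
    if sign not in (1, -1):
        raise ConfigurationError(f"sign must be +1 or -1, got {sign}")
    return SagittalTrace(
        sample_rate=series.sample_rate,
        av=sign * series.gyro[:, _AXES[axis]],
        t0=series.t0,
    )
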