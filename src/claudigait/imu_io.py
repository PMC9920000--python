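"""Reading, writing and uniform resampling of smartphone IMU CSV logs.

Smartphone sensor loggers (HyperIMU-style) emit one CSV row per sensor event:
a timestamp plus three columns per sensor (accelerometer in m/s^2, gyroscope in
rad/s, magnetometer in uT).  Because the OS delivers sensor events only when
values change appreciably, the inter-sample spacing is irregular; every
downstream stage assumes a uniform 50 Hz grid, obtained here by per-channel
linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_COLUMNS = (
    "timestamp",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)


class ImuFormatError(ValueError):
    """Raised when a CSV log does not match the expected dialect."""


@dataclass
class RawImuRecording:
    """Irregularly-timestamped 9-axis sensor log in the phone body frame.

    timestamps are seconds, strictly increasing after deduplication; accel is
    m/s^2, gyro rad/s, mag uT, each with shape (n, 3).
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = self.timestamps.shape[0]
        for name in ("accel", "gyro", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def span(self) -> float:
        """Duration in seconds from first to last sample."""
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UniformImuRecording:
    """9-axis recording on a uniform grid start_time + k / rate."""

    rate: float
    start_time: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.accel.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate


def read_imu_csv(path, columns=DEFAULT_COLUMNS, timestamp_unit: str = "auto") -> RawImuRecording:
    """Read a one-row-per-sample IMU CSV into a :class:`RawImuRecording`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header naming (at least) the ten required columns.
    columns : sequence of str
        Names of the timestamp column and the nine sensor columns, in the
        order timestamp, acc_xyz, gyr_xyz, mag_xyz.
    timestamp_unit : {"auto", "s", "ms"}
        "auto" treats timestamps as milliseconds when the median raw spacing
        exceeds 1 (HyperIMU logs epoch milliseconds); the decision is recorded
        in ``meta["timestamp_unit"]``.

    Rows with unparseable cells are dropped and counted in
    ``meta["dropped_rows"]``; duplicate timestamps keep the last sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ImuFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[list(columns)].apply(pd.to_numeric, errors="coerce")
    n_total = len(df)
    df = df.dropna()
    dropped = n_total - len(df)
    # OS-batched events can repeat a timestamp; the last write wins.
    df = df.sort_values(columns[0], kind="stable").drop_duplicates(columns[0], keep="last")
    if len(df) < 2:
        raise ImuFormatError("fewer than 2 valid rows in recording")

    ts = df[columns[0]].to_numpy(dtype=float)
    if timestamp_unit == "auto":
        unit = "ms" if float(np.median(np.diff(ts))) > 1.0 else "s"
    else:
        unit = timestamp_unit
    if unit == "ms":
        ts = ts / 1000.0

    meta = {"dropped_rows": int(dropped), "timestamp_unit": unit, "source": str(path)}
    return RawImuRecording(
        timestamps=ts,
        accel=df[list(columns[1:4])].to_numpy(dtype=float),
        gyro=df[list(columns[4:7])].to_numpy(dtype=float),
        mag=df[list(columns[7:10])].to_numpy(dtype=float),
        meta=meta,
    )


def write_imu_csv(path, rec: RawImuRecording, columns=DEFAULT_COLUMNS, fmt: str = "%.9f") -> None:
    """Write a recording in the default CSV dialect (fixed decimal format)."""
    data = np.column_stack([rec.timestamps, rec.accel, rec.gyro, rec.mag])
    header = ",".join(columns)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt=fmt)


def resample_linear(raw: RawImuRecording, rate: float = 50.0) -> UniformImuRecording:
    """Linearly interpolate every channel onto a uniform grid at ``rate`` Hz.

    The grid is ``t0 + k/rate`` for ``k = 0 .. floor(span*rate)``, clipped to
    the observed span (no extrapolation).
    """
    ts = raw.timestamps
    if len(ts) < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    span = float(ts[-1] - ts[0])
    if span < 1.0 / rate:
        raise ValueError(f"recording span {span:.4g} s is shorter than one sample period")

    n_grid = int(math.floor(span * rate + 1e-9)) + 1
    grid = ts[0] + np.arange(n_grid) / rate

    def interp(block: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(grid, ts, block[:, j]) for j in range(3)])

    meta = dict(raw.meta)
    meta["resampled_from_n"] = len(ts)
    return UniformImuRecording(
        rate=float(rate),
        start_time=float(ts[0]),
        accel=interp(raw.accel),
        gyro=interp(raw.gyro),
        mag=interp(raw.mag),
        meta=meta,
    )
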