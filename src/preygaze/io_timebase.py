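"""Raw-file readers and the common 60 Hz timebase.

The pipeline starts from three kinds of raw input:

* per-frame 2-D landmark tables (markerless-tracker CSV dialect with three
  header rows: scorer / bodyparts / coords, then x, y, likelihood triplets),
* inertial voltage series (3-axis accelerometer + 3-axis gyroscope, nominally
  50 Hz) converted to physical units by supplied linear gains,
* a plain-text config of rates, gains and thresholds.

Because the overhead camera, the two eye cameras and the IMU are acquired on
independent clocks, every channel is linearly interpolated onto one uniform
timebase (default 60 Hz) before any kinematic quantity is computed. No
extrapolation is performed: target samples outside a source stream's span, or
inside a dropped-frame gap, come back as NaN and stay masked downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import unwrap_degrees, wrap_degrees
from .exceptions import FormatError

__all__ = [
    "LandmarkSeries",
    "ImuSeries",
    "TimeSeries",
    "ChannelSet",
    "load_landmarks",
    "load_imu",
    "median_filter_series",
    "median_window_samples",
    "resample_linear",
    "build_channelset",
]


@dataclass
class LandmarkSeries:
    """Timestamped named 2-D points with confidences from one camera."""

    timestamps: np.ndarray                 # (n,) seconds, strictly increasing
    points: dict[str, np.ndarray]          # name -> (n, 2) pixels; NaN = missing
    confidence: dict[str, np.ndarray]      # name -> (n,) in [0, 1]
    frame_rate: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        n = self.timestamps.size
        for name, xy in self.points.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (n, 2):
                raise ValueError(f"point {name!r}: expected shape {(n, 2)}")
            self.points[name] = xy
        for name, c in self.confidence.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (n,):
                raise ValueError(f"confidence {name!r}: expected shape {(n,)}")
            if np.any((c < 0) | (c > 1)):
                raise ValueError(f"confidence {name!r} outside [0, 1]")
            self.confidence[name] = c
        if set(self.points) != set(self.confidence):
            raise ValueError("points and confidence must share the same names")

    @property
    def names(self) -> list[str]:
        return list(self.points)

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)


@dataclass
class ImuSeries:
    """Inertial series in physical units (m/s^2 and rad/s)."""

    timestamps: np.ndarray      # (n,) seconds
    accel: np.ndarray           # (n, 3) m/s^2
    gyro: np.ndarray            # (n, 3) rad/s
    sample_rate: float = 50.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        n = self.timestamps.size
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3)")


@dataclass
class TimeSeries:
    """One scalar stream with its own timestamps, before resampling."""

    timestamps: np.ndarray
    values: np.ndarray
    angle: bool = False     # unwrap before interpolation, re-wrap after

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must match in shape")


@dataclass
class ChannelSet:
    """Named scalar series sharing one uniform timestamp vector."""

    timestamps: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    rate: float = 60.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.timestamps.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = v

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.timestamps, **self.channels})


def load_landmarks(path, dialect: str = "tracker-csv",
                   frame_rate: float = 60.0) -> LandmarkSeries:
    """Read a markerless-tracker landmark CSV.

    The dialect has three header rows (scorer, bodyparts, coords) above one
    row per frame; each bodypart contributes an x, y, likelihood triplet and
    the first column is the frame index. Missing cells are flagged invalid
    (NaN coordinates, confidence 0) rather than dropped.
    """
    if dialect != "tracker-csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header_lines = [fh.readline().rstrip("\n") for _ in range(3)]
    if any(not line for line in header_lines):
        raise FormatError(f"{path}: expected three header rows")
    counts = [len(line.split(",")) for line in header_lines]
    if len(set(counts)) != 1:
        raise FormatError(f"{path}: header rows disagree in column count {counts}")
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse tracker CSV: {exc}") from exc
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    seen: dict[str, int] = {}
    for bp in df.columns.get_level_values(1):
        seen[bp] = seen.get(bp, 0) + 1
    if any(count != 3 for count in seen.values()):
        raise FormatError(
            f"{path}: each bodypart needs exactly x, y, likelihood columns; got {seen}"
        )
    frames = df.index.to_numpy(dtype=float)
    timestamps = frames / float(frame_rate)
    points: dict[str, np.ndarray] = {}
    confidence: dict[str, np.ndarray] = {}
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        missing = {"x", "y", "likelihood"} - set(sub.columns)
        if missing:
            raise FormatError(f"{path}: bodypart {bp!r} lacks columns {sorted(missing)}")
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        like = sub["likelihood"].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        like = np.where(bad | ~np.isfinite(like), 0.0, like)
        xy[bad] = np.nan
        points[bp] = xy
        confidence[bp] = np.clip(like, 0.0, 1.0)
    return LandmarkSeries(timestamps, points, confidence, frame_rate=frame_rate)


_IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def load_imu(path, accel_gains, gyro_gains, sample_rate: float = 50.0) -> ImuSeries:
    """Read an IMU CSV (columns t, ax..az, gx..gz in volts) and convert units.

    ``accel_gains`` / ``gyro_gains`` are per-channel linear factors
    (m/s^2 per volt, rad/s per volt). The gyroscope is converted without any
    filtering; accelerometer smoothing happens later in the kinematics stage.
    """
    df = pd.read_csv(path)
    missing = set(_IMU_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing IMU channels {sorted(missing)}")
    accel_gains = np.asarray(accel_gains, dtype=float).reshape(3)
    gyro_gains = np.asarray(gyro_gains, dtype=float).reshape(3)
    t = df["t"].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float) * accel_gains
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * gyro_gains
    return ImuSeries(t, accel, gyro, sample_rate=sample_rate)


def median_window_samples(window_ms: float, rate: float) -> int:
    """Convert a window in milliseconds to the nearest odd sample count >= 1."""
    w = window_ms / 1000.0 * rate
    k = int(round(w))
    if k % 2 == 0:
        k += 1 if w >= k else -1
    return max(k, 1)


def median_filter_series(x, window_ms: float, rate: float) -> np.ndarray:
    """Sliding-window median with the window shrinking at the series ends.

    NaN (invalid) samples are ignored inside each window but stay NaN in the
    output so masking propagates.
    """
    x = np.asarray(x, dtype=float)
    if window_ms <= 0:
        raise ValueError("window must be positive")
    k = median_window_samples(window_ms, rate)
    if k <= 1:
        warnings.warn("median window shorter than one sample; returning input")
        return x.copy()
    out = (
        pd.Series(x)
        .rolling(window=k, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    out[~np.isfinite(x)] = np.nan
    return out


def resample_linear(values, timestamps, target=60.0, *, angle: bool = False,
                    max_gap_factor: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate one stream onto a uniform grid (no extrapolation).

    ``target`` is either a rate in Hz (grid spans the stream itself) or an
    explicit array of target timestamps. Returns ``(grid, values_on_grid)``;
    samples outside the valid source span, or bridging a dropped-frame gap
    longer than ``max_gap_factor`` median source intervals, are NaN.
    """
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size != x.size:
        raise ValueError("values and timestamps must match in length")
    if t.size < 2:
        raise ValueError("need at least two samples to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.isscalar(target):
        rate = float(target)
        if rate <= 0:
            raise ValueError("target rate must be positive")
        n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
        grid = t[0] + np.arange(n) / rate
    else:
        grid = np.asarray(target, dtype=float)

    valid = np.isfinite(x)
    out = np.full(grid.shape, np.nan)
    if valid.sum() >= 2:
        tv, xv = t[valid], x[valid]
        if angle:
            xv = unwrap_degrees(xv)
        inside = (grid >= tv[0]) & (grid <= tv[-1])
        out[inside] = np.interp(grid[inside], tv, xv)
        # mask samples interpolated across a dropped-frame gap
        dt_nominal = float(np.median(np.diff(t)))
        gaps = np.flatnonzero(np.diff(tv) > max_gap_factor * dt_nominal)
        for g in gaps:
            out[(grid > tv[g]) & (grid < tv[g + 1])] = np.nan
        if angle:
            finite = np.isfinite(out)
            out[finite] = wrap_degrees(out[finite])
    return grid, out


def build_channelset(streams: dict[str, TimeSeries], target_rate: float = 60.0,
                     ) -> ChannelSet:
    """Resample named streams onto one shared grid spanning their overlap.

    Angle-valued streams (``TimeSeries.angle``) are unwrapped before
    interpolation and re-wrapped to (-180, 180] afterwards.
    """
    if not streams:
        raise ValueError("no streams given")
    start = max(s.timestamps[0] for s in streams.values())
    end = min(s.timestamps[-1] for s in streams.values())
    if end <= start:
        raise ValueError("streams have no overlapping time range")
    n = int(np.floor((end - start) * target_rate + 1e-9)) + 1
    grid = start + np.arange(n) / target_rate
    channels = {}
    for name, s in streams.items():
        _, channels[name] = resample_linear(
            s.values, s.timestamps, grid, angle=s.angle
        )
    return ChannelSet(grid, channels, rate=target_rate)
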