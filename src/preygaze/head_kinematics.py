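"""Head pose from overhead landmarks, locomotion speed, cricket geometry,
and inertial (pitch / yaw-rate) processing.

Head position and yaw come from fitting the eight tracked head points of
each frame to a mean head geometry by a rigid 2-D transform (translation +
rotation, no scaling); yaw is referenced to the nose-to-head-center line so
that 0 deg means the head axis points along the arena +x axis, positive
counter-clockwise from above. Cricket-relative geometry (distance, azimuth,
range rate) and locomotion speed feed the behavioral epoch definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import unwrap_degrees, wrap_degrees
from .exceptions import AnalysisError, FitError
from .io_timebase import LandmarkSeries, ImuSeries, median_filter_series

__all__ = [
    "HeadTemplate",
    "HeadPoseSeries",
    "TargetGeometrySeries",
    "ImuDerived",
    "ImuAxisMap",
    "compute_mean_geometry",
    "fit_rigid_pose",
    "fit_head_poses",
    "compute_speed",
    "target_geometry",
    "process_imu",
    "estimate_head_measurement_error",
]

GRAVITY = 9.80665  # m/s^2


@dataclass
class HeadTemplate:
    """Mean head geometry: named 2-D points, centroid at the origin."""

    names: list[str]
    coords: np.ndarray  # (k, 2)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("coords must be (len(names), 2)")
        if len(self.names) < 3:
            raise ValueError("template needs >=3 points")
        sv = np.linalg.svd(self.coords - self.coords.mean(axis=0),
                           compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1e-30):
            raise ValueError("template points are collinear")

    def reference_angle(self, reference=("nose", "head_center")) -> float:
        """Direction (deg) of the nose-to-head-center line in template coords."""
        a, b = reference
        if a in self.names and b in self.names:
            v = self.coords[self.names.index(a)] - self.coords[self.names.index(b)]
            return float(np.degrees(np.arctan2(v[1], v[0])))
        return 0.0


@dataclass
class HeadPoseSeries:
    """Per-frame head center (cm), yaw (deg, wrapped), fit residual, validity."""

    x: np.ndarray
    y: np.ndarray
    yaw: np.ndarray
    residual: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        for name in ("x", "y", "yaw", "residual"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class TargetGeometrySeries:
    """Cricket-relative geometry: distance (cm), azimuth (deg, 0 = head
    pointed at cricket, positive = cricket right of the head axis), and the
    smoothed range rate (cm/s, negative while closing)."""

    distance: np.ndarray
    azimuth: np.ndarray
    range_rate: np.ndarray


@dataclass
class ImuDerived:
    """Gravity-derived head orientation and gyroscope yaw rate."""

    pitch: np.ndarray      # deg, positive nose-up
    roll: np.ndarray       # deg
    yaw_rate: np.ndarray   # deg/s
    clipped: np.ndarray = field(default=None)  # samples where |a| > g

    def __post_init__(self):
        if self.clipped is None:
            self.clipped = np.zeros(np.asarray(self.pitch).shape, dtype=bool)


@dataclass
class ImuAxisMap:
    """Which sensor axis is forward / lateral / yaw, with signs."""

    forward: tuple[int, int] = (0, 1)   # (channel index, sign)
    lateral: tuple[int, int] = (1, 1)
    yaw_gyro: tuple[int, int] = (2, 1)


def _valid_points(points, confidence, conf_threshold):
    pts = np.asarray(points, dtype=float)
    ok = np.isfinite(pts).all(axis=1)
    w = np.ones(pts.shape[0]) if confidence is None else np.asarray(confidence, float)
    w = np.where(ok & (w >= conf_threshold), w, 0.0)
    return pts, w


def fit_rigid_pose(frame_points, template: HeadTemplate, confidence=None,
                   conf_threshold: float = 0.9,
                   reference=("nose", "head_center")):
    """Closed-form weighted rigid 2-D fit of one frame to the template.

    Returns ``(x, y, yaw_deg, residual)``; yaw is the template rotation plus
    the template's nose-to-head-center direction, wrapped to (-180, 180].
    Frames with fewer than two usable points come back as all-NaN (invalid).
    """
    pts, w = _valid_points(frame_points, confidence, conf_threshold)
    use = w > 0
    if use.sum() < 2:
        return np.nan, np.nan, np.nan, np.nan
    a = template.coords[use]
    b = pts[use]
    ww = w[use][:, None]
    ca = (ww * a).sum(axis=0) / ww.sum()
    cb = (ww * b).sum(axis=0) / ww.sum()
    a0, b0 = a - ca, b - cb
    # rotation maximizing sum w * <R a0, b0>: angle from the cross-covariance
    s = float(np.sum(ww[:, 0] * (a0 * b0).sum(axis=1)))
    c = float(np.sum(ww[:, 0] * (a0[:, 0] * b0[:, 1] - a0[:, 1] * b0[:, 0])))
    ang = np.arctan2(c, s)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = cb - R @ ca
    resid = np.sqrt(
        float(np.sum(ww[:, 0] * ((a @ R.T + t - b) ** 2).sum(axis=1)) / ww.sum())
    )
    yaw = wrap_degrees(np.degrees(ang) + template.reference_angle(reference))
    # head center = image of the template origin (= template centroid)
    return float(t[0]), float(t[1]), float(yaw), float(resid)


def compute_mean_geometry(landmarks: LandmarkSeries, n_iter: int = 50,
                          tol: float = 1e-6,
                          conf_threshold: float = 0.9) -> HeadTemplate:
    """Generalized-Procrustes mean head shape (rotation + translation only).

    Frames are iteratively aligned to the running mean and averaged until the
    mean moves by less than ``tol`` (RMS) or ``n_iter`` is reached.
    """
    names = landmarks.names
    pts = np.stack([landmarks.points[nm] for nm in names], axis=1)   # (n, k, 2)
    conf = np.stack([landmarks.confidence[nm] for nm in names], axis=1)
    ok = np.isfinite(pts).all(axis=2) & (conf >= conf_threshold)
    usable = np.flatnonzero(ok.sum(axis=1) >= 3)
    if usable.size < 10:
        raise FitError(f"need >=10 frames with >=3 valid points, got {usable.size}")

    # initialize from the frame with the most valid points
    init = usable[np.argmax(ok[usable].sum(axis=1))]
    template = pts[init].copy()
    missing0 = ~ok[init]
    template[missing0] = np.nanmean(
        np.where(ok[..., None], pts, np.nan), axis=0
    )[missing0]
    template -= np.nanmean(template, axis=0)
    tmpl = HeadTemplate(names, np.nan_to_num(template))

    for _ in range(n_iter):
        aligned = np.full_like(pts[usable], np.nan)
        for j, i in enumerate(usable):
            res = fit_rigid_pose(pts[i], tmpl, conf[i], conf_threshold,
                                 reference=("", ""))
            if not np.isfinite(res[2]):
                continue
            ang = np.deg2rad(res[2])
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            t = np.array([res[0], res[1]])
            # map frame points back into template space
            back = (pts[i] - t) @ R
            back[~ok[i]] = np.nan
            aligned[j] = back
        new = np.nanmean(aligned, axis=0)
        if np.isnan(new).any():
            raise FitError("some template points never observed")
        new -= new.mean(axis=0)
        change = np.sqrt(np.mean((new - tmpl.coords) ** 2))
        tmpl = HeadTemplate(names, new)
        if change < tol:
            break
    return tmpl


def fit_head_poses(landmarks: LandmarkSeries, template: HeadTemplate,
                   conf_threshold: float = 0.9,
                   reference=("nose", "head_center")) -> HeadPoseSeries:
    """Fit every frame of a landmark series to the template."""
    names = template.names
    n = landmarks.n_frames
    out = np.full((n, 4), np.nan)
    pts = np.stack([landmarks.points[nm] for nm in names], axis=1)
    conf = np.stack([landmarks.confidence[nm] for nm in names], axis=1)
    for i in range(n):
        out[i] = fit_rigid_pose(pts[i], template, conf[i], conf_threshold,
                                reference)
    valid = np.isfinite(out[:, 2])
    return HeadPoseSeries(out[:, 0], out[:, 1], out[:, 2], out[:, 3], valid)


def compute_speed(x, y, rate: float, window_ms: float = 500.0) -> np.ndarray:
    """Locomotion speed (cm/s): frame-to-frame displacement x rate, then a
    500 ms median filter. The first sample repeats the first displacement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 samples")
    step = np.hypot(np.diff(x), np.diff(y)) * rate
    speed = np.concatenate([step[:1], step])
    return median_filter_series(speed, window_ms, rate)


def target_geometry(head: HeadPoseSeries, cricket_xy, rate: float,
                    window_ms: float = 500.0,
                    azimuth_sign: int = 1) -> TargetGeometrySeries:
    """Distance, azimuth and smoothed range rate of the cricket.

    Azimuth = yaw - bearing(head center -> cricket), wrapped; with yaw
    counter-clockwise-positive this makes azimuth positive when the cricket
    is to the right of the head axis (``azimuth_sign`` flips it). Range rate
    is the central-difference derivative of distance passed through the same
    500 ms median filter as speed.
    """
    cricket = np.asarray(cricket_xy, dtype=float)
    dx = cricket[:, 0] - head.x
    dy = cricket[:, 1] - head.y
    distance = np.hypot(dx, dy)
    bearing = np.degrees(np.arctan2(dy, dx))
    azimuth = azimuth_sign * wrap_degrees(head.yaw - bearing)
    rr = np.gradient(distance) * rate
    range_rate = median_filter_series(rr, window_ms, rate)
    bad = ~head.valid | ~np.isfinite(cricket).all(axis=1)
    for arr in (distance, azimuth, range_rate):
        arr[bad] = np.nan
    return TargetGeometrySeries(distance, azimuth, range_rate)


def process_imu(imu: ImuSeries, axis_map: ImuAxisMap | None = None,
                window_ms: float = 266.7, g: float = GRAVITY) -> ImuDerived:
    """Head orientation from filtered accelerometry and gyro yaw rate.

    Accelerometer channels are median filtered (266.7 ms) to remove rapid
    transients, then gravity tilt is extracted: pitch = asin(a_forward / g),
    roll = asin(a_lateral / g). Gyroscope channels stay unfiltered; the yaw
    axis is converted to deg/s. Samples with |a| > g are clipped and flagged.
    """
    axis_map = axis_map or ImuAxisMap()
    acc = np.stack(
        [median_filter_series(imu.accel[:, i], window_ms, imu.sample_rate)
         for i in range(3)],
        axis=1,
    )
    fi, fs = axis_map.forward
    li, ls = axis_map.lateral
    uf = fs * acc[:, fi] / g
    ul = ls * acc[:, li] / g
    clipped = (np.abs(uf) > 1.0) | (np.abs(ul) > 1.0)
    pitch = np.degrees(np.arcsin(np.clip(uf, -1.0, 1.0)))
    roll = np.degrees(np.arcsin(np.clip(ul, -1.0, 1.0)))
    yi, ys = axis_map.yaw_gyro
    yaw_rate = np.degrees(ys * imu.gyro[:, yi])
    return ImuDerived(pitch, roll, yaw_rate, clipped)


def estimate_head_measurement_error(yaw_rate_imu, yaw_landmark,
                                    rate: float) -> float:
    """RMS difference (deg per frame) of the two independent head-yaw
    rotation estimates: landmark-fit frame-to-frame rotation vs the
    integrated gyroscope yaw rate."""
    yaw_rate_imu = np.asarray(yaw_rate_imu, dtype=float)
    dyaw_lm = np.diff(unwrap_degrees(np.asarray(yaw_landmark, dtype=float)))
    dyaw_imu = yaw_rate_imu[:-1] / rate
    diff = dyaw_lm - dyaw_imu
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        raise AnalysisError("no overlapping valid samples")
    return float(np.sqrt(np.mean(diff**2)))


def kinematic_table(t, **channels) -> pd.DataFrame:
    """Assemble the standard per-session kinematics table (CSV-exportable)."""
    return pd.DataFrame({"t": np.asarray(t, dtype=float), **channels})
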