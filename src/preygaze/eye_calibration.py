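"""Pupil-ellipse fitting and eye-camera calibration.

Head-mounted eye cameras cannot be calibrated by directed fixation, so the
angular scale is recovered from the geometry of the imaged pupil itself.
Under a spherical-eye model, the pupil is circular when the eye points along
the camera's optical axis and flattens into an ellipse as it rotates away:
for an angular offset theta from the axis, the pupil's ellipticity (minor /
major axis ratio) is cos(theta) and its center is displaced by R*sin(theta)
pixels, where R is the effective rotation radius in pixels.

Two quantities therefore calibrate each camera:

* the camera-axis center ``c`` — the image point where the pupil would appear
  circular. Each sufficiently elliptical frame constrains ``c`` to the line
  through the pupil center along the ellipse's major axis (the major axis is
  perpendicular to the vector from pupil center to ``c``); stacking frames
  gives an overdetermined linear system solved by least squares.
* the scale factor ``R`` — from |p - c| = R*sqrt(1 - e^2), fit as a
  through-origin least-squares slope across frames.

Angular eye position then follows as theta = asin(|p - c| / R) per image
axis, and central (0 deg) eye position is defined as the mean pupil location
over the recording.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError, CalibrationError, FitError

__all__ = [
    "Ellipse",
    "CameraCalibration",
    "EyeAngleSeries",
    "fit_pupil_ellipse",
    "fit_pupil_ellipses",
    "estimate_camera_center",
    "estimate_scale",
    "calibrate_eye",
    "pupil_to_angle",
    "center_eye_positions",
    "estimate_eye_measurement_error",
]


@dataclass(frozen=True)
class Ellipse:
    """Geometric ellipse: center (px), semi-axes a >= b (px), major-axis
    orientation phi in (-90, 90] degrees."""

    center: tuple[float, float]
    a: float
    b: float
    phi: float

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")

    @property
    def ellipticity(self) -> float:
        """Minor/major axis ratio in (0, 1]; cos of the off-axis angle."""
        return self.b / self.a

    @property
    def major_axis(self) -> np.ndarray:
        """Unit vector along the major axis."""
        phi = np.deg2rad(self.phi)
        return np.array([np.cos(phi), np.sin(phi)])


@dataclass
class CameraCalibration:
    """Per-eye calibration: camera-axis center and angular scale factor."""

    center: np.ndarray        # (2,) pixels
    scale: float              # R, pixels (must be > 0)
    n_frames_used: int = 0
    residual: float = 0.0     # RMS of the perpendicularity constraints, px

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.scale <= 0:
            raise ValueError("scale factor R must be positive")

    def to_json(self, path=None) -> str:
        doc = {
            "camera_axis_center_px": list(self.center),
            "scale_factor_px": self.scale,
            "n_frames_used": self.n_frames_used,
            "residual_px": self.residual,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class EyeAngleSeries:
    """Horizontal/vertical eye-in-head angles (degrees) with a validity mask.

    Both eyes are expressed in a shared head frame where positive theta_h is
    rightward; the per-eye image-to-head sign map is applied upstream.
    """

    theta_h: np.ndarray
    theta_v: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.theta_h = np.asarray(self.theta_h, dtype=float)
        self.theta_v = np.asarray(self.theta_v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.theta_h.shape == self.theta_v.shape == self.valid.shape):
            raise ValueError("component shapes must match")


# ---------------------------------------------------------------------------
# Ellipse fitting (direct algebraic least squares, Halir & Flusser scheme)
# ---------------------------------------------------------------------------

def _conic_to_ellipse(coef: np.ndarray) -> Ellipse:
    """Convert conic coefficients (A, B, C, D, E, F) to geometric form."""
    A, B, C, D, E, F = coef
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        center = np.linalg.solve(2.0 * Q, -np.array([D, E]))
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate conic (singular quadratic part)") from exc
    k = center @ Q @ center + D * center[0] + E * center[1] + F
    evals, evecs = np.linalg.eigh(Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        axes_sq = -k / evals
    if not np.all(axes_sq > 0):
        raise FitError("fit is not an ellipse (hyperbolic or degenerate)")
    axes = np.sqrt(axes_sq)
    major = int(np.argmax(axes))
    a, b = float(axes[major]), float(axes[1 - major])
    v = evecs[:, major]
    phi = float(np.rad2deg(np.arctan2(v[1], v[0])))
    if phi <= -90.0:
        phi += 180.0
    elif phi > 90.0:
        phi -= 180.0
    return Ellipse((float(center[0]), float(center[1])), a, b, phi)


def _direct_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stabilized direct algebraic fit with the hard ellipse constraint
    4AC - B^2 > 0 (Halir-Flusser scheme)."""
    D1 = np.column_stack([x**2, x * y, y**2])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate edge-point configuration") from exc
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    candidates = np.flatnonzero(np.isreal(evals) & (cond > 0))
    if candidates.size == 0:
        raise FitError("no ellipse solution (degenerate fit)")
    a1 = np.real(evecs[:, candidates[0]])
    return np.concatenate([a1, T @ a1])


def _taubin_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient-normalized (Taubin) conic least squares.

    Same algebraic residual as the direct fit but normalized by the conic
    gradient, which removes the leading noise-induced flattening bias that
    few-point direct fits show. Closed form via a 6x6 generalized
    eigenproblem; the most-elliptical admissible eigenvector is taken.
    """
    from scipy.linalg import eig as geig
    one = np.ones_like(x)
    zero = np.zeros_like(x)
    Z = np.column_stack([x * x, x * y, y * y, x, y, one])
    M = Z.T @ Z / x.size
    Jx = np.column_stack([2 * x, y, zero, one, zero, zero])
    Jy = np.column_stack([zero, x, 2 * y, zero, one, zero])
    N = (Jx.T @ Jx + Jy.T @ Jy) / x.size
    with np.errstate(all="ignore"):
        evals, evecs = geig(M, N)
    evals = np.real(evals)
    order = np.argsort(np.where(np.isfinite(evals), np.abs(evals), np.inf))
    for k in order:
        a = np.real(evecs[:, k])
        if 4.0 * a[0] * a[2] - a[1] ** 2 > 0:
            return a
    raise FitError("no ellipse solution (degenerate fit)")


def fit_pupil_ellipse(edge_points, confidence=None,
                      conf_threshold: float = 0.9,
                      method: str = "taubin") -> Ellipse:
    """Least-squares ellipse through pupil-edge points.

    ``method='taubin'`` (default) uses gradient-normalized algebraic least
    squares, which is closed-form and nearly unbiased for the 8-point,
    sub-pixel-noise regime of pupil tracking; ``method='direct'`` is the
    plain direct algebraic fit with the hard ellipse constraint. Needs at
    least 5 valid, non-collinear points; degenerate input raises
    :class:`FitError`.
    """
    pts = np.asarray(edge_points, dtype=float).reshape(-1, 2)
    valid = np.isfinite(pts).all(axis=1)
    if confidence is not None:
        valid &= np.asarray(confidence, dtype=float) >= conf_threshold
    pts = pts[valid]
    if pts.shape[0] < 5:
        raise FitError(f"need >=5 valid edge points, got {pts.shape[0]}")
    mean = pts.mean(axis=0)
    centered = pts - mean
    scale = np.sqrt((centered**2).sum(axis=1).mean())
    if scale <= 0:
        raise FitError("all edge points coincide")
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * sv[0]:
        raise FitError("edge points are collinear")
    x, y = (centered / scale).T
    if method == "direct":
        coef = _direct_conic(x, y)
    elif method == "taubin":
        coef = _taubin_conic(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    ell = _conic_to_ellipse(coef)
    # undo normalization
    cx, cy = np.array(ell.center) * scale + mean
    return Ellipse((float(cx), float(cy)), ell.a * scale, ell.b * scale, ell.phi)


def fit_pupil_ellipses(points, confidence=None, conf_threshold: float = 0.9,
                       method: str = "taubin") -> list[Ellipse | None]:
    """Fit each frame of an (n, k, 2) edge-point array; failures become None."""
    points = np.asarray(points, dtype=float)
    out: list[Ellipse | None] = []
    for i in range(points.shape[0]):
        conf = None if confidence is None else confidence[i]
        try:
            out.append(fit_pupil_ellipse(points[i], conf, conf_threshold,
                                         method))
        except FitError:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# Camera-axis center and scale factor
# ---------------------------------------------------------------------------

def _select_frames(ellipses, min_eccentricity: float) -> list[Ellipse]:
    """Frames with significant ellipticity: e <= 1 - min_eccentricity."""
    return [
        e for e in ellipses
        if e is not None and e.ellipticity <= 1.0 - min_eccentricity
    ]


def estimate_camera_center(ellipses, min_eccentricity: float = 0.01,
                           cond_cap: float = 1e8,
                           full_output: bool = False):
    """Least-squares camera-axis center from the major-axis constraints.

    For every selected frame the major axis m_i is perpendicular to
    (c - p_i), so m_i . c = m_i . p_i; the stacked system is solved directly.
    """
    sel = _select_frames(ellipses, min_eccentricity)
    if len(sel) < 2:
        raise CalibrationError(
            f"need >=2 frames with e <= {1 - min_eccentricity:.3f}, got {len(sel)}"
        )
    M = np.array([e.major_axis for e in sel])
    d = np.array([e.major_axis @ np.asarray(e.center) for e in sel])
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > cond_cap:
        raise CalibrationError("major axes nearly parallel; center ill-conditioned")
    center, *_ = np.linalg.lstsq(M, d, rcond=None)
    residual = float(np.sqrt(np.mean((M @ center - d) ** 2)))
    if full_output:
        return center, residual, len(sel)
    return center


def estimate_scale(ellipses, center, min_eccentricity: float = 0.01,
                   regression: str = "slope") -> float:
    """Scale factor R from |p_i - c| = R * sqrt(1 - e_i^2).

    ``regression='slope'`` is the through-origin least-squares slope of
    displacement against sqrt(1 - e^2). ``regression='inverse'`` fits the
    reciprocal relation (sqrt(1 - e^2) against displacement) and inverts it:
    with tracking noise, e is the noisy variable while the pupil-center
    displacement is comparatively clean, so putting the noise on the
    response side avoids the attenuation bias of the plain slope.
    """
    sel = _select_frames(ellipses, min_eccentricity)
    if not sel:
        raise CalibrationError("no sufficiently elliptical frames for scale")
    center = np.asarray(center, dtype=float)
    s = np.array([np.sqrt(max(0.0, 1.0 - e.ellipticity**2)) for e in sel])
    d = np.array([np.linalg.norm(np.asarray(e.center) - center) for e in sel])
    if float(np.sum(s**2)) <= 0:
        raise CalibrationError("all selected frames circular; scale undefined")
    if regression == "slope":
        return float(np.sum(d * s) / np.sum(s**2))
    if regression == "inverse":
        num = float(np.sum(s * d))
        if num <= 0:
            raise CalibrationError("degenerate scale regression")
        return float(np.sum(d**2) / num)
    raise ValueError(f"unknown regression {regression!r}")


def calibrate_eye(ellipses, min_eccentricity: float = 0.01,
                  regression: str = "slope") -> CameraCalibration:
    """Run center then scale estimation over a session's pupil ellipses."""
    if not any(e is not None for e in ellipses):
        raise CalibrationError("no valid ellipses to calibrate from")
    center, residual, n_used = estimate_camera_center(
        ellipses, min_eccentricity, full_output=True
    )
    scale = estimate_scale(ellipses, center, min_eccentricity, regression)
    return CameraCalibration(center, scale, n_frames_used=n_used,
                             residual=residual)


def pupil_to_angle(p, cal: CameraCalibration, sign_h: int = 1, sign_v: int = 1):
    """Convert pupil center(s) to angular eye position in degrees.

    theta = asin((p - c) / R) per image axis; ``sign_h``/``sign_v`` map
    camera-frame image axes onto the shared rightward/upward-positive head
    frame (the two eyes view the head from opposite sides, so one eye's
    horizontal sign is flipped in config). Displacements numerically outside
    the model sphere (|p - c| > R) are clipped with a warning.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    u = (p - cal.center) / cal.scale
    if np.nanmax(np.abs(u), initial=0.0) > 1.0 + 1e-12:
        warnings.warn("pupil displacement outside calibration sphere; clipping")
    u = np.clip(u, -1.0, 1.0)
    theta_h = sign_h * np.degrees(np.arcsin(u[:, 0]))
    theta_v = sign_v * np.degrees(np.arcsin(u[:, 1]))
    if single:
        return float(theta_h[0]), float(theta_v[0])
    return theta_h, theta_v


def center_eye_positions(series: EyeAngleSeries) -> EyeAngleSeries:
    """Re-reference to central (0 deg) eye position = mean over valid samples."""
    valid = series.valid & np.isfinite(series.theta_h) & np.isfinite(series.theta_v)
    if not valid.any():
        raise AnalysisError("no valid samples to define central eye position")
    return EyeAngleSeries(
        series.theta_h - series.theta_h[valid].mean(),
        series.theta_v - series.theta_v[valid].mean(),
        series.valid.copy(),
    )


def estimate_eye_measurement_error(theta_h, speed, head_yaw, *,
                                   speed_threshold: float = 1.0,
                                   rotation_threshold: float = 1.0,
                                   method: str = "frame_diff") -> float:
    """Upper-bound eye measurement error from stationary periods, in degrees.

    Restricted to samples where speed < ``speed_threshold`` (cm/s) and the
    frame-to-frame head rotation is < ``rotation_threshold`` (deg), when true
    eye movement is minimal. ``method='frame_diff'`` returns
    std(frame-to-frame difference)/sqrt(2), unbiased for iid noise;
    ``method='window_std'`` pools the position std within stationary runs.
    """
    theta_h = np.asarray(theta_h, dtype=float)
    speed = np.asarray(speed, dtype=float)
    head_yaw = np.asarray(head_yaw, dtype=float)
    stationary = (speed < speed_threshold) & np.isfinite(theta_h)
    dyaw = np.abs(np.diff(head_yaw))
    pair_ok = stationary[:-1] & stationary[1:] & (dyaw < rotation_threshold)
    if method == "frame_diff":
        d = np.diff(theta_h)[pair_ok]
        d = d[np.isfinite(d)]
        if d.size < 2:
            raise AnalysisError("no stationary frame pairs")
        return float(np.std(d, ddof=1) / np.sqrt(2.0))
    if method == "window_std":
        mask = np.zeros_like(stationary)
        idx = np.flatnonzero(pair_ok)
        mask[idx] = True
        mask[idx + 1] = True
        vals = theta_h[mask]
        if vals.size < 2:
            raise AnalysisError("no stationary samples")
        # pool variance within contiguous stationary runs
        runs = np.split(np.flatnonzero(mask), np.flatnonzero(np.diff(np.flatnonzero(mask)) > 1) + 1)
        sq, n = 0.0, 0
        for run in runs:
            if run.size >= 2:
                v = theta_h[run]
                sq += np.sum((v - v.mean()) ** 2)
                n += run.size - 1
        if n == 0:
            raise AnalysisError("stationary runs too short")
        return float(np.sqrt(sq / n))
    raise ValueError(f"unknown method {method!r}")
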