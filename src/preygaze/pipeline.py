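"""End-to-end session analysis over a channel dictionary.

Ties the stages together for scripts, tests and the acceptance harness:
given synchronized 60 Hz channels (head x/y/yaw, pitch, per-eye horizontal
angles, cricket position), derive speed and cricket geometry, detect
behavioral epochs, run the gaze segmentation, and compute the headline
summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import unwrap_degrees, wrap_degrees
from .epochs import EpochSet, detect_approaches, detect_moving, epoch_mask
from .gaze_dynamics import (GazeSeries, run_gaze_pipeline, rms_stabilization)
from .head_kinematics import (HeadPoseSeries, TargetGeometrySeries,
                              compute_speed, target_geometry)
from .stats import lagged_xcorr, pitch_vergence_fit, pre_post_saccade_stats

__all__ = ["SessionAnalysis", "analyze_channels", "summary_statistics"]


@dataclass
class SessionAnalysis:
    """Derived channels, epochs, gaze segmentation and summary statistics."""

    t: np.ndarray
    rate: float
    speed: np.ndarray
    geometry: TargetGeometrySeries
    moving: EpochSet
    approaches: EpochSet
    approaches_raw: EpochSet       # conjunction only, no post-processing
    gaze: GazeSeries
    head_azimuth: np.ndarray       # deg, cricket relative to head axis
    gaze_azimuth: np.ndarray       # deg, cricket relative to gaze direction
    rms_head: np.ndarray = None
    rms_gaze: np.ndarray = None
    rms_head_median: float = np.nan
    rms_gaze_median: float = np.nan


def analyze_channels(channels: dict, rate: float = 60.0,
                     gaze_threshold: float = 180.0,
                     min_fixation_ms: float = 50.0) -> SessionAnalysis:
    """Run the full analysis on one session's synchronized channels.

    ``channels`` needs x, y, yaw (deg; wrapped or unwrapped), theta_r,
    theta_l, pitch, cricket_x, cricket_y. Yaw is unwrapped internally; all
    gaze quantities stay on the unwrapped line.
    """
    t = channels.get("t")
    n = np.asarray(channels["yaw"]).size
    if t is None:
        t = np.arange(n) / rate
    yaw_u = unwrap_degrees(np.asarray(channels["yaw"], dtype=float))
    speed = compute_speed(channels["x"], channels["y"], rate)
    pose = HeadPoseSeries(channels["x"], channels["y"], wrap_degrees(yaw_u),
                          np.zeros(n), np.isfinite(yaw_u))
    cricket = np.stack([channels["cricket_x"], channels["cricket_y"]], axis=-1)
    geometry = target_geometry(pose, cricket, rate)
    moving = detect_moving(speed, rate, t0=t[0])
    approaches = detect_approaches(speed, geometry.azimuth,
                                   geometry.range_rate, rate, t0=t[0])
    approaches_raw = detect_approaches(speed, geometry.azimuth,
                                       geometry.range_rate, rate,
                                       merge_gap=0.0, min_duration=0.0,
                                       t0=t[0])
    gaze = run_gaze_pipeline(channels["theta_r"], channels["theta_l"], yaw_u,
                             rate, threshold=gaze_threshold,
                             min_fixation_ms=min_fixation_ms, t0=t[0])
    # gaze azimuth: where the gaze points relative to the cricket; since
    # azimuth = yaw - bearing, the gaze version just adds the mean eye angle
    gaze_azimuth = geometry.azimuth + gaze.mean_eye
    result = SessionAnalysis(t, rate, speed, geometry, moving, approaches,
                             approaches_raw, gaze, geometry.azimuth,
                             gaze_azimuth)
    if gaze.fixations.n:
        result.rms_gaze, result.rms_gaze_median = rms_stabilization(
            gaze.gaze, gaze.fixations, rate, t0=t[0])
        result.rms_head, result.rms_head_median = rms_stabilization(
            yaw_u, gaze.fixations, rate, t0=t[0])
    return result


def summary_statistics(analysis: SessionAnalysis, pitch=None,
                       max_lag: float = 2.0) -> dict:
    """Headline statistics of one analyzed session."""
    a = analysis
    out = {
        "n_saccades": a.gaze.saccades.n,
        "n_fixations": a.gaze.fixations.n,
        "fixation_median_ms": float(np.median(a.gaze.fixations.durations_ms))
        if a.gaze.fixations.n else np.nan,
        "rms_head_median_deg": a.rms_head_median,
        "rms_gaze_median_deg": a.rms_gaze_median,
        "n_approach_epochs": a.approaches.n,
        "approach_time_s": a.approaches.total_duration,
    }
    yaw_u = a.gaze.gaze - a.gaze.mean_eye
    hx = lagged_xcorr(yaw_u, a.gaze.mean_eye, a.rate, max_lag, mode="diff_both")
    out["head_eye_xcorr_lag0"] = hx.at_lag(0.0)
    if pitch is not None:
        slope, intercept, r = pitch_vergence_fit(pitch, a.gaze.vergence)
        out["pitch_vergence_slope"] = slope
        out["pitch_vergence_r"] = r
    if a.gaze.saccades.n:
        from .exceptions import AnalysisError
        mask = epoch_mask(a.approaches, a.t)
        try:
            pp = pre_post_saccade_stats(
                np.abs(a.head_azimuth), np.abs(a.gaze_azimuth),
                a.gaze.saccades.onsets, a.rate, t0=a.t[0], mask=mask)
            for key in ("pre_head_median", "pre_gaze_median",
                        "post_head_median", "post_gaze_median", "n_saccades"):
                out[f"targeting_{key}"] = pp[key]
        except AnalysisError:
            pass
    return out
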