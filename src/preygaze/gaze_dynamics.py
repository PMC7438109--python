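"""Gaze reconstruction and saccade/fixation segmentation.

Gaze G is the world-referenced viewing direction: the sum of head yaw H and
the mean horizontal eye-in-head angle E = (theta_R + theta_L) / 2 (averaging
removes vergence, the anti-conjugate component V = theta_R - theta_L).
Samples are classified by gaze velocity: |dG/dt| above a fixed +-180 deg/s
threshold is saccadic (non-compensatory, gaze-shifting), everything else is
compensatory (VOR-stabilized). Maximal compensatory runs are fixations;
maximal saccadic runs (merged across single-sample dropouts, which the
central-difference velocity estimator creates) are saccades with an onset,
amplitude, peak velocity and direction. Per-fixation RMS deviation of gaze
vs head yaw quantifies how much stabler the gaze is than the head.

All head/gaze angle series here are assumed unwrapped (no +-180 seam);
wrapping happens only at export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AnalysisError

__all__ = [
    "COMPENSATORY", "SACCADIC", "INVALID",
    "FixationSet", "SaccadeSet", "GazeSeries",
    "compute_vergence", "compute_mean_eye", "compute_gaze",
    "compute_velocity", "classify_gaze_samples",
    "segment_fixations", "detect_saccades", "rms_stabilization",
    "run_gaze_pipeline",
]

COMPENSATORY = 0
SACCADIC = 1
INVALID = -1

GAZE_VELOCITY_THRESHOLD = 180.0  # deg/s


@dataclass
class FixationSet:
    """Half-open fixation intervals (s) with durations in ms."""

    intervals: np.ndarray        # (m, 2) seconds
    durations_ms: np.ndarray     # (m,)

    @property
    def n(self) -> int:
        return int(self.intervals.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_s": self.intervals[:, 0],
            "end_s": self.intervals[:, 1],
            "duration_ms": self.durations_ms,
        })


@dataclass
class SaccadeSet:
    """Detected gaze-shifting events."""

    onsets: np.ndarray            # (m,) seconds
    amplitudes: np.ndarray        # (m,) degrees, signed delta-G across the run
    peak_velocities: np.ndarray   # (m,) deg/s, signed at the fastest sample
    onset_indices: np.ndarray     # (m,) sample indices
    end_indices: np.ndarray       # (m,) last saccadic sample of each run

    @property
    def n(self) -> int:
        return int(self.onsets.size)

    @property
    def directions(self) -> np.ndarray:
        return np.sign(self.amplitudes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onsets,
            "amplitude_deg": self.amplitudes,
            "peak_velocity_dps": self.peak_velocities,
            "direction": self.directions,
        })


@dataclass
class GazeSeries:
    """Bundled result of the gaze pipeline on one session."""

    vergence: np.ndarray
    mean_eye: np.ndarray
    gaze: np.ndarray
    gaze_velocity: np.ndarray
    labels: np.ndarray
    fixations: FixationSet = None
    saccades: SaccadeSet = None
    rate: float = 60.0


def _check_same_length(*arrays):
    n = {np.asarray(a).shape[0] for a in arrays}
    if len(n) != 1:
        raise ValueError(f"series length mismatch: {sorted(n)}")


def compute_vergence(theta_r, theta_l) -> np.ndarray:
    """Vergence V = theta_R - theta_L (deg); negative = converged (both eyes
    rotated nasally), positive = diverged."""
    theta_r = np.asarray(theta_r, dtype=float)
    theta_l = np.asarray(theta_l, dtype=float)
    _check_same_length(theta_r, theta_l)
    return theta_r - theta_l


def compute_mean_eye(theta_r, theta_l) -> np.ndarray:
    """Mean horizontal eye position E = (theta_R + theta_L) / 2 (deg)."""
    theta_r = np.asarray(theta_r, dtype=float)
    theta_l = np.asarray(theta_l, dtype=float)
    _check_same_length(theta_r, theta_l)
    return 0.5 * (theta_r + theta_l)


def compute_gaze(yaw_unwrapped, mean_eye) -> np.ndarray:
    """Gaze direction G = H + E on the unwrapped line (deg)."""
    yaw = np.asarray(yaw_unwrapped, dtype=float)
    e = np.asarray(mean_eye, dtype=float)
    _check_same_length(yaw, e)
    return yaw + e


def compute_velocity(x, rate: float) -> np.ndarray:
    """Angular velocity (deg/s): central differences, one-sided at the ends."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need >=3 samples for a velocity estimate")
    return np.gradient(x) * rate


def classify_gaze_samples(gaze_velocity,
                          threshold: float = GAZE_VELOCITY_THRESHOLD
                          ) -> np.ndarray:
    """Label samples: |velocity| strictly above threshold -> SACCADIC, other
    finite samples -> COMPENSATORY, NaN -> INVALID."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(gaze_velocity, dtype=float)
    labels = np.full(v.shape, INVALID, dtype=int)
    finite = np.isfinite(v)
    labels[finite] = np.where(np.abs(v[finite]) > threshold, SACCADIC,
                              COMPENSATORY)
    return labels


def _runs(condition: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open index pairs."""
    padded = np.concatenate([[False], condition, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def segment_fixations(labels, rate: float, min_duration_ms: float = 50.0,
                      t0: float = 0.0) -> FixationSet:
    """Maximal compensatory runs of at least ``min_duration_ms``."""
    labels = np.asarray(labels)
    runs = [
        (s, e) for s, e in _runs(labels == COMPENSATORY)
        if (e - s) / rate * 1000.0 >= min_duration_ms
    ]
    if not runs:
        return FixationSet(np.empty((0, 2)), np.empty(0))
    iv = np.array([[t0 + s / rate, t0 + e / rate] for s, e in runs])
    return FixationSet(iv, (iv[:, 1] - iv[:, 0]) * 1000.0)


def detect_saccades(labels, gaze, gaze_velocity, rate: float,
                    merge_gap_samples: int = 1, t0: float = 0.0) -> SaccadeSet:
    """One saccade per maximal saccadic run.

    Runs separated by <= ``merge_gap_samples`` non-saccadic samples are
    merged (the central-difference velocity can dip below threshold for a
    single frame mid-shift). Onset is the first suprathreshold sample;
    amplitude is G at the last run sample minus G just before onset.
    """
    labels = np.asarray(labels)
    gaze = np.asarray(gaze, dtype=float)
    v = np.asarray(gaze_velocity, dtype=float)
    runs = _runs(labels == SACCADIC)
    if merge_gap_samples > 0 and len(runs) > 1:
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            gap = slice(merged[-1][1], s)
            if (s - merged[-1][1] <= merge_gap_samples
                    and not np.any(labels[gap] == INVALID)):
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]
    if not runs:
        return SaccadeSet(*(np.empty(0),) * 3, np.empty(0, int), np.empty(0, int))
    onset_idx = np.array([s for s, _ in runs], dtype=int)
    end_idx = np.array([e - 1 for _, e in runs], dtype=int)
    pre_idx = np.maximum(onset_idx - 1, 0)
    amplitudes = gaze[end_idx] - gaze[pre_idx]
    peaks = np.array([v[s:e][np.argmax(np.abs(v[s:e]))] for s, e in runs])
    return SaccadeSet(t0 + onset_idx / rate, amplitudes, peaks,
                      onset_idx, end_idx)


def saccade_amplitudes_plateau(gaze, labels, saccades: SaccadeSet,
                               max_flank: int = 12) -> np.ndarray:
    """Noise-robust saccade amplitudes from the flanking fixation plateaus.

    During a fixation the VOR holds gaze constant, so the best estimate of
    the pre- and post-saccade gaze level is the mean over the adjacent
    compensatory samples (up to ``max_flank`` on each side, stopping at any
    non-compensatory sample). The single-sample amplitude in
    :class:`SaccadeSet` is kept as the operational definition; this
    estimator is preferred when comparing against ground truth under
    measurement noise.
    """
    gaze = np.asarray(gaze, dtype=float)
    labels = np.asarray(labels)
    out = np.full(saccades.n, np.nan)
    for k in range(saccades.n):
        s, e = saccades.onset_indices[k], saccades.end_indices[k]
        pre = []
        i = s - 1
        while i >= 0 and labels[i] == COMPENSATORY and len(pre) < max_flank:
            pre.append(gaze[i])
            i -= 1
        post = []
        i = e + 1
        while (i < gaze.size and labels[i] == COMPENSATORY
               and len(post) < max_flank):
            post.append(gaze[i])
            i += 1
        if pre and post:
            out[k] = np.mean(post) - np.mean(pre)
        else:
            out[k] = saccades.amplitudes[k]
    return out


def rms_stabilization(x, fixations: FixationSet, rate: float,
                      t0: float = 0.0) -> tuple[np.ndarray, float]:
    """Per-fixation RMS deviation of ``x`` about its within-fixation mean.

    Returns (per-fixation RMS array, median). The same estimator applied to
    gaze and to head yaw quantifies how much the VOR stabilizes gaze.
    """
    if fixations.n == 0:
        raise AnalysisError("no fixations")
    x = np.asarray(x, dtype=float)
    out = np.full(fixations.n, np.nan)
    for i, (s, e) in enumerate(fixations.intervals):
        i0 = int(round((s - t0) * rate))
        i1 = int(round((e - t0) * rate))
        seg = x[i0:i1]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = np.sqrt(np.mean((seg - seg.mean()) ** 2))
    if not np.isfinite(out).any():
        raise AnalysisError("no valid samples inside fixations")
    return out, float(np.nanmedian(out))


def run_gaze_pipeline(theta_r, theta_l, yaw_unwrapped, rate: float = 60.0,
                      threshold: float = GAZE_VELOCITY_THRESHOLD,
                      min_fixation_ms: float = 50.0,
                      merge_gap_samples: int = 1,
                      t0: float = 0.0) -> GazeSeries:
    """Full horizontal-gaze analysis of one session's eye and head channels."""
    vergence = compute_vergence(theta_r, theta_l)
    mean_eye = compute_mean_eye(theta_r, theta_l)
    gaze = compute_gaze(yaw_unwrapped, mean_eye)
    velocity = compute_velocity(gaze, rate)
    labels = classify_gaze_samples(velocity, threshold)
    fixations = segment_fixations(labels, rate, min_fixation_ms, t0)
    saccades = detect_saccades(labels, gaze, velocity, rate,
                               merge_gap_samples, t0)
    return GazeSeries(vergence, mean_eye, gaze, velocity, labels,
                      fixations, saccades, rate)
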