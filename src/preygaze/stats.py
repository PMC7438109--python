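"""Session-level summary statistics.

Lagged cross-correlations (eye-eye coupling, head-eye compensation,
azimuth-tracking), saccade-triggered averages of head and gaze azimuth,
pre/post-saccade targeting distributions, the pitch-vergence regression, and
conditional distributions. Masked statistics (e.g. approach-only) are always
computed within mask-contiguous segments and combined by sample-weighted
averaging, never across epoch boundaries, so approach and non-approach
regimes do not mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import AnalysisError

__all__ = [
    "LagCorrelation",
    "TriggeredAverage",
    "lagged_xcorr",
    "triggered_average",
    "pre_post_saccade_stats",
    "pitch_vergence_fit",
    "masked_distribution",
]


@dataclass
class LagCorrelation:
    """Pearson correlation per integer-sample lag on a symmetric grid."""

    lags: np.ndarray   # seconds; positive lag means b follows a
    r: np.ndarray
    n: np.ndarray      # samples contributing per lag

    def at_lag(self, lag_s: float) -> float:
        return float(self.r[np.argmin(np.abs(self.lags - lag_s))])


@dataclass
class TriggeredAverage:
    """Event-aligned mean trace with dispersion."""

    offsets: np.ndarray  # seconds, includes 0 (event onset)
    mean: np.ndarray
    sem: np.ndarray
    n_events: int


def _segments(mask: np.ndarray) -> list[slice]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [slice(s, e) for s, e in zip(edges[::2], edges[1::2])]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def lagged_xcorr(a, b, rate: float, max_lag: float, mode: str = "raw",
                 mask=None) -> LagCorrelation:
    """Time-lagged Pearson cross-correlation of two synchronized series.

    ``mode`` applies first differencing before correlating: 'raw', 'diff_a',
    'diff_b' or 'diff_both'. Positive lag means ``b`` follows ``a``. With a
    mask, each contiguous masked segment is correlated separately (after
    within-segment differencing) and segments are combined per lag by
    sample-weighted averaging of r.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if mode not in ("raw", "diff_a", "diff_b", "diff_both"):
        raise ValueError(f"unknown mode {mode!r}")
    valid = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    L = int(round(max_lag * rate))
    lags = np.arange(-L, L + 1)
    r_sum = np.zeros(lags.size)
    w_sum = np.zeros(lags.size)
    for seg in _segments(valid):
        xa, xb = a[seg], b[seg]
        if mode in ("diff_a", "diff_both"):
            xa = np.diff(xa)
        if mode in ("diff_b", "diff_both"):
            xb = np.diff(xb)
        m = min(xa.size, xb.size)
        xa, xb = xa[:m], xb[:m]
        for j, lag in enumerate(lags):
            if abs(lag) >= m:
                continue
            if lag >= 0:
                x, y = xa[: m - lag], xb[lag:]
            else:
                x, y = xa[-lag:], xb[: m + lag]
            if x.size < 2:
                continue
            r = _pearson(x, y)
            if np.isfinite(r):
                r_sum[j] += r * x.size
                w_sum[j] += x.size
    if not np.any(w_sum > 0):
        raise AnalysisError("no segment long enough for any lag")
    with np.errstate(invalid="ignore"):
        r = np.where(w_sum > 0, r_sum / np.maximum(w_sum, 1), np.nan)
    return LagCorrelation(lags / rate, r, w_sum)


def triggered_average(x, rate: float, events, window=(0.5, 0.5),
                      transform: str = "identity", t0: float = 0.0,
                      drop_partial: bool = True) -> TriggeredAverage:
    """Average of ``x`` aligned to event times.

    ``window`` is (pre, post) in seconds; offset 0 is the event onset.
    ``transform='abs'`` rectifies the signal before averaging (used for
    azimuth traces around saccades). Events whose window leaves the valid
    data are dropped when ``drop_partial``.
    """
    x = np.asarray(x, dtype=float)
    events = np.atleast_1d(np.asarray(events, dtype=float))
    pre, post = window
    k_pre, k_post = int(round(pre * rate)), int(round(post * rate))
    offsets = np.arange(-k_pre, k_post + 1)
    if transform == "abs":
        x = np.abs(x)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    rows = []
    for e in events:
        i = int(round((e - t0) * rate))
        lo, hi = i - k_pre, i + k_post + 1
        if lo < 0 or hi > x.size:
            if drop_partial:
                continue
            row = np.full(offsets.size, np.nan)
            src_lo, src_hi = max(lo, 0), min(hi, x.size)
            row[src_lo - lo: src_hi - lo] = x[src_lo:src_hi]
        else:
            row = x[lo:hi]
        rows.append(row)
    if not rows:
        raise AnalysisError("no events with a usable window")
    stack = np.array(rows)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        n_per = np.sum(np.isfinite(stack), axis=0)
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n_per, 1))
    return TriggeredAverage(offsets / rate, mean, sem, len(rows))


def pre_post_saccade_stats(abs_head_azimuth, abs_gaze_azimuth, onsets,
                           rate: float, pre_offset: float = 0.1,
                           post_offset: float = 0.05, t0: float = 0.0,
                           mask=None) -> dict:
    """Head vs gaze targeting accuracy sampled around saccade onsets.

    Samples |azimuth| of head and gaze at onset - pre_offset and
    onset + post_offset for every saccade (optionally restricted to a mask,
    e.g. approach epochs) and returns the four distributions with their
    medians and standard errors. The defaults sample inside the pre-saccadic
    stabilization period (100 ms before onset, while the head turns and the
    gaze lags) and just after the shift completes (50 ms), before the next
    compensatory drift accumulates.
    """
    head = np.asarray(abs_head_azimuth, dtype=float)
    gaze = np.asarray(abs_gaze_azimuth, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    out = {"pre_head": [], "pre_gaze": [], "post_head": [], "post_gaze": []}
    for onset in onsets:
        i = int(round((onset - t0) * rate))
        if mask is not None and (i < 0 or i >= head.size
                                 or not np.asarray(mask, bool)[i]):
            continue
        i_pre = i - int(round(pre_offset * rate))
        i_post = i + int(round(post_offset * rate))
        if i_pre < 0 or i_post >= head.size:
            continue
        if not (np.isfinite(head[i_pre]) and np.isfinite(gaze[i_pre])
                and np.isfinite(head[i_post]) and np.isfinite(gaze[i_post])):
            continue
        out["pre_head"].append(head[i_pre])
        out["pre_gaze"].append(gaze[i_pre])
        out["post_head"].append(head[i_post])
        out["post_gaze"].append(gaze[i_post])
    if not out["pre_head"]:
        raise AnalysisError("no saccades with usable pre/post samples")
    result = {}
    for key, vals in out.items():
        arr = np.array(vals)
        result[key] = arr
        result[f"{key}_median"] = float(np.median(arr))
        result[f"{key}_sem"] = float(np.std(arr, ddof=1) / np.sqrt(arr.size))
    result["n_saccades"] = len(out["pre_head"])
    return result


def pitch_vergence_fit(pitch, vergence, mask=None):
    """OLS line vergence = slope * pitch + intercept, plus Pearson r.

    Captures the pitch-vergence coupling: as the head pitches down the eyes
    diverge (move temporally), vertically stabilizing the scene.
    """
    p = np.asarray(pitch, dtype=float)
    v = np.asarray(vergence, dtype=float)
    ok = np.isfinite(p) & np.isfinite(v)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    p, v = p[ok], v[ok]
    if p.size < 3 or p.std() == 0:
        raise AnalysisError("need >=3 samples with pitch variance > 0")
    fit = sps.linregress(p, v)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def masked_distribution(x, mask, bins=None, bin_width: float | None = None):
    """Histogram and median of ``x`` restricted to a condition mask.

    Returns (counts, bin_edges, median).
    """
    x = np.asarray(x, dtype=float)
    sel = x[np.asarray(mask, dtype=bool) & np.isfinite(x)]
    if sel.size == 0:
        raise AnalysisError("empty mask")
    if bins is None:
        if bin_width is not None:
            lo = np.floor(sel.min() / bin_width) * bin_width
            hi = np.ceil(sel.max() / bin_width) * bin_width + bin_width / 2
            bins = np.arange(lo, hi + bin_width, bin_width)
        else:
            bins = 50
    counts, edges = np.histogram(sel, bins=bins)
    return counts, edges, float(np.median(sel))
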