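#!/usr/bin/env python
"""Session-level summary statistics and figures.

Computes the coupling statistics the study design centers on — eye-eye and
head-eye lagged cross-correlations, the pitch-vergence regression,
saccade-triggered azimuth averages, and pre/post-saccade targeting medians
— and writes summary.json plus (if matplotlib is available) a small set of
figures under <session-dir>/figures.

    python analysis/05_summary_statistics.py --session-dir results/session
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from preygaze.epochs import epoch_mask
from preygaze.gaze_dynamics import COMPENSATORY
from preygaze.pipeline import analyze_channels
from preygaze.stats import (lagged_xcorr, pitch_vergence_fit,
                            pre_post_saccade_stats, triggered_average)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session-dir", default="results/session")
    ap.add_argument("--no-figures", action="store_true")
    args = ap.parse_args()
    d = args.session_dir

    table = pd.read_csv(f"{d}/kinematics.csv")
    ch = {c: table[c].to_numpy() for c in table.columns}
    ana = analyze_channels(ch)
    comp = ana.gaze.labels == COMPENSATORY

    summary = {}
    ee = lagged_xcorr(ch["theta_r"], ch["theta_l"], 60.0, 1.0,
                      mode="diff_both")
    hx = lagged_xcorr(ch["yaw"], ana.gaze.mean_eye, 60.0, 1.0,
                      mode="diff_both", mask=comp)
    summary["eye_eye_delta_r_lag0"] = ee.at_lag(0.0)
    summary["head_eye_delta_r_lag0_compensatory"] = hx.at_lag(0.0)

    slope, intercept, r = pitch_vergence_fit(ch["pitch"], ana.gaze.vergence)
    summary["pitch_vergence_slope"] = slope
    summary["pitch_vergence_r"] = r

    amask = epoch_mask(ana.approaches, ana.t)
    onsets = ana.gaze.saccades.onsets
    in_app = onsets[epoch_mask(ana.approaches, onsets)]
    stats_out = {}
    if in_app.size:
        ta_head = triggered_average(ana.head_azimuth, 60.0, in_app,
                                    window=(0.5, 0.5), transform="abs")
        ta_gaze = triggered_average(ana.gaze_azimuth, 60.0, in_app,
                                    window=(0.5, 0.5), transform="abs")
        pp = pre_post_saccade_stats(np.abs(ana.head_azimuth),
                                    np.abs(ana.gaze_azimuth), onsets, 60.0,
                                    mask=amask)
        for key in ("pre_head_median", "pre_gaze_median", "post_head_median",
                    "post_gaze_median", "n_saccades"):
            summary[f"targeting_{key}"] = pp[key]
        stats_out["triggered"] = (ta_head, ta_gaze)

    summary["n_saccades"] = int(ana.gaze.saccades.n)
    summary["n_fixations"] = int(ana.gaze.fixations.n)
    summary["fixation_median_ms"] = float(
        np.median(ana.gaze.fixations.durations_ms))
    summary["rms_head_median_deg"] = ana.rms_head_median
    summary["rms_gaze_median_deg"] = ana.rms_gaze_median

    with open(f"{d}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    for k, v in summary.items():
        print(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")

    if args.no_figures:
        return
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    os.makedirs(f"{d}/figures", exist_ok=True)

    fig, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    ax[0].plot(ee.lags, ee.r)
    ax[0].set(title="eye-eye delta xcorr", xlabel="lag (s)", ylabel="r")
    ax[1].plot(hx.lags, hx.r)
    ax[1].set(title="head-eye delta xcorr (compensatory)", xlabel="lag (s)")
    fig.tight_layout()
    fig.savefig(f"{d}/figures/crosscorrelations.png", dpi=120)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    sel = np.isfinite(ch["pitch"]) & np.isfinite(ana.gaze.vergence)
    ax.plot(ch["pitch"][sel][::20], ana.gaze.vergence[sel][::20], ".",
            ms=2, alpha=0.3)
    px = np.linspace(np.nanmin(ch["pitch"]), np.nanmax(ch["pitch"]), 2)
    ax.plot(px, slope * px + intercept, "r-")
    ax.set(xlabel="head pitch (deg)", ylabel="vergence (deg)",
           title=f"slope {slope:.2f}, r {r:.2f}")
    fig.tight_layout()
    fig.savefig(f"{d}/figures/pitch_vergence.png", dpi=120)

    if "triggered" in stats_out:
        ta_head, ta_gaze = stats_out["triggered"]
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.plot(ta_head.offsets, ta_head.mean, label="|head azimuth|")
        ax.plot(ta_gaze.offsets, ta_gaze.mean, label="|gaze azimuth|")
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time from saccade onset (s)", ylabel="deg")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{d}/figures/saccade_triggered_azimuth.png", dpi=120)
    print(f"figures under {d}/figures")


if __name__ == "__main__":
    main()
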