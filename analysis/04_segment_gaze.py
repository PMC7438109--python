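#!/usr/bin/env python
"""Detect behavioral epochs and segment gaze into saccades and fixations.

Runs on the reconstructed kinematics table: derives speed and cricket
geometry, labels moving/approach epochs, reconstructs gaze G = H + E,
classifies samples at the +-180 deg/s gaze-velocity threshold, and writes
the saccade/fixation/epoch tables. Recovered events are compared to the
bundle's ground truth when present.

    python analysis/04_segment_gaze.py --session-dir results/session
"""

import argparse
import json

import numpy as np
import pandas as pd

from preygaze.pipeline import analyze_channels


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session-dir", default="results/session")
    args = ap.parse_args()
    d = args.session_dir

    table = pd.read_csv(f"{d}/kinematics.csv")
    ana = analyze_channels({c: table[c].to_numpy() for c in table.columns})

    ana.gaze.saccades.to_frame().to_csv(f"{d}/saccades.csv", index=False)
    fx = ana.gaze.fixations.to_frame()
    fx["rms_gaze_deg"] = ana.rms_gaze
    fx["rms_head_deg"] = ana.rms_head
    fx.to_csv(f"{d}/fixations.csv", index=False)
    ana.approaches.to_bed(f"{d}/approach_epochs.bed")
    ana.moving.to_bed(f"{d}/moving_epochs.bed")

    print(f"saccades: {ana.gaze.saccades.n}, fixations: {ana.gaze.fixations.n} "
          f"(median {np.median(ana.gaze.fixations.durations_ms):.0f} ms)")
    print(f"median per-fixation RMS: head {ana.rms_head_median:.2f} deg, "
          f"gaze {ana.rms_gaze_median:.2f} deg")
    print(f"approach epochs: {ana.approaches.n} "
          f"({ana.approaches.total_duration:.1f} s)")

    try:
        gt = json.load(open(f"{d}/ground_truth.json"))
    except FileNotFoundError:
        return
    truth_t = np.array(gt["saccade_onsets_s"])
    det_t = ana.gaze.saccades.onsets
    hits = np.array([np.any(np.abs(det_t - o) <= 1.5 / 60) for o in truth_t])
    print(f"vs ground truth: {hits.mean() * 100:.1f}% of {truth_t.size} true "
          f"saccade onsets recovered within one frame")


if __name__ == "__main__":
    main()
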