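#!/usr/bin/env python
"""Calibrate both eye cameras from the tracked pupil-edge points.

For each eye: fit per-frame pupil ellipses, estimate the camera-axis center
from the major-axis perpendicularity constraint, estimate the pixels-per-
rotation scale factor, and write a calibration report. If the session bundle
carries ground truth, the recovered geometry is compared against it.

    python analysis/02_calibrate_eyes.py --session-dir results/session
"""

import argparse
import json

import numpy as np

from preygaze.eye_calibration import calibrate_eye, fit_pupil_ellipses
from preygaze.io_timebase import load_landmarks


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session-dir", default="results/session")
    ap.add_argument("--min-eccentricity", type=float, default=0.05,
                    help="frames with e <= 1 - this are used (noisy tracker "
                         "data wants a stricter cut than the noiseless 0.01)")
    args = ap.parse_args()
    d = args.session_dir

    truth = None
    try:
        truth = json.load(open(f"{d}/ground_truth.json")).get("calibration")
    except FileNotFoundError:
        pass

    for eye in ("right", "left"):
        lm = load_landmarks(f"{d}/eye_{eye}.csv", frame_rate=60.0)
        pts = np.stack([lm.points[f"pupil_{k}"] for k in range(8)], axis=1)
        ells = fit_pupil_ellipses(pts)
        cal = calibrate_eye(ells, min_eccentricity=args.min_eccentricity,
                            regression="inverse")
        cal.to_json(f"{d}/calibration_{eye}.json")
        print(f"{eye} eye: center ({cal.center[0]:.1f}, {cal.center[1]:.1f}) px, "
              f"R {cal.scale:.1f} px, {cal.n_frames_used} frames, "
              f"residual {cal.residual:.2f} px")
        if truth:
            tc = np.array(truth[eye]["center"])
            print(f"  vs truth: center off "
                  f"{np.linalg.norm(cal.center - tc):.2f} px, "
                  f"scale off {abs(cal.scale - truth[eye]['scale']):.2f} px")


if __name__ == "__main__":
    main()
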