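#!/usr/bin/env python
"""Rebuild the common 60 Hz kinematics table from the raw-style files.

Overhead landmarks (30 Hz) are fit to a mean head geometry for position and
yaw; IMU voltages (50 Hz) give pitch and gyro yaw rate; eye-camera landmarks
(60 Hz) pass through ellipse fitting and the saved calibrations to angular
eye position. Everything is linearly interpolated onto one 60 Hz timebase
and written as kinematics.csv.

    python analysis/03_reconstruct_kinematics.py --session-dir results/session
"""

import argparse
import json

import numpy as np

from preygaze.eye_calibration import (CameraCalibration, EyeAngleSeries,
                                      center_eye_positions,
                                      fit_pupil_ellipses, pupil_to_angle)
from preygaze.head_kinematics import (compute_mean_geometry, fit_head_poses,
                                      process_imu)
from preygaze.io_timebase import (LandmarkSeries, TimeSeries,
                                  build_channelset, load_imu, load_landmarks)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session-dir", default="results/session")
    args = ap.parse_args()
    d = args.session_dir
    meta = json.load(open(f"{d}/session_meta.json"))

    # head + cricket from the overhead camera
    lm = load_landmarks(f"{d}/overhead.csv", frame_rate=meta["overhead_rate"])
    head_names = list(meta["template"])
    head = LandmarkSeries(lm.timestamps,
                          {k: lm.points[k] for k in head_names},
                          {k: lm.confidence[k] for k in head_names},
                          meta["overhead_rate"])
    template = compute_mean_geometry(head)
    poses = fit_head_poses(head, template)
    print(f"head poses: {poses.valid.sum()}/{poses.valid.size} frames valid, "
          f"median residual {np.nanmedian(poses.residual):.3f}")

    # inertial channels
    imu = load_imu(f"{d}/imu.csv", [meta["accel_gain"]] * 3,
                   [meta["gyro_gain"]] * 3, sample_rate=meta["imu_rate"])
    derived = process_imu(imu)

    # eyes through the saved calibrations
    eye_angles = {}
    for eye in ("right", "left"):
        cal_doc = json.load(open(f"{d}/calibration_{eye}.json"))
        cal = CameraCalibration(cal_doc["camera_axis_center_px"],
                                cal_doc["scale_factor_px"])
        elm = load_landmarks(f"{d}/eye_{eye}.csv", frame_rate=60.0)
        pts = np.stack([elm.points[f"pupil_{k}"] for k in range(8)], axis=1)
        ells = fit_pupil_ellipses(pts)
        centers = np.array([e.center if e else (np.nan, np.nan) for e in ells])
        th, tv = pupil_to_angle(centers, cal, sign_h=meta["eye_sign"][eye])
        centered = center_eye_positions(
            EyeAngleSeries(th, tv, np.isfinite(th)))
        eye_angles[eye] = (elm.timestamps, centered.theta_h)

    streams = {
        "x": TimeSeries(lm.timestamps, poses.x),
        "y": TimeSeries(lm.timestamps, poses.y),
        "yaw": TimeSeries(lm.timestamps, poses.yaw, angle=True),
        "cricket_x": TimeSeries(lm.timestamps, lm.points["cricket_body"][:, 0]),
        "cricket_y": TimeSeries(lm.timestamps, lm.points["cricket_body"][:, 1]),
        "pitch": TimeSeries(imu.timestamps, derived.pitch),
        "yaw_rate_imu": TimeSeries(imu.timestamps, derived.yaw_rate),
        "theta_r": TimeSeries(*eye_angles["right"]),
        "theta_l": TimeSeries(*eye_angles["left"]),
    }
    cs = build_channelset(streams, target_rate=60.0)
    cs.to_frame().to_csv(f"{d}/kinematics.csv", index=False)
    print(f"wrote {d}/kinematics.csv: {cs.timestamps.size} samples at 60 Hz, "
          f"channels {sorted(cs.channels)}")


if __name__ == "__main__":
    main()
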