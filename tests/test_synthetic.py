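import json

import numpy as np
import pytest

from preygaze.angles import wrap_degrees
from preygaze.epochs import detect_approaches
from preygaze.eye_calibration import (calibrate_eye, fit_pupil_ellipses,
                                      pupil_to_angle)
from preygaze.head_kinematics import (compute_mean_geometry, compute_speed,
                                      fit_head_poses, process_imu)
from preygaze.io_timebase import LandmarkSeries, load_imu, load_landmarks
from preygaze.pipeline import analyze_channels
from preygaze.synthetic import (DEFAULT_HEAD_TEMPLATE, SimulationParams,
                                export_raw_style, project_pupil,
                                simulate_session)


class TestDeterminism:
    def test_same_seed_is_bitwise_identical(self):
        p = SimulationParams(duration=20.0, seed=42)
        s1 = simulate_session(p)
        s2 = simulate_session(SimulationParams(duration=20.0, seed=42))
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name],
                                          s2.channels[name])
        np.testing.assert_array_equal(s1.ground_truth.saccade_onset_frames,
                                      s2.ground_truth.saccade_onset_frames)
        m1, m2 = s1.measured(), s2.measured()
        np.testing.assert_array_equal(m1["theta_r"], m2["theta_r"])

    def test_different_seeds_differ(self):
        s1 = simulate_session(SimulationParams(duration=20.0, seed=1))
        s2 = simulate_session(SimulationParams(duration=20.0, seed=2))
        assert not np.array_equal(s1.channels["yaw"], s2.channels["yaw"])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(SimulationParams(duration=-5.0))
        with pytest.raises(ValueError):
            simulate_session(SimulationParams(vor_gain=-1.0))


class TestPerfectVorLimit:
    def test_gaze_constant_and_no_saccades(self, perfect_vor_session):
        s = perfect_vor_session
        g = s.channels["gaze"]
        assert np.max(np.abs(g - g[0])) < 1e-9
        assert s.ground_truth.saccade_onset_frames.size == 0
        # head must actually move for the limit to be informative
        assert np.std(s.channels["yaw"]) > 1.0


class TestGroundTruthConsistency:
    def test_fixations_and_saccades_partition_time(self, default_session):
        gt = default_session.ground_truth
        d = default_session.params.saccade_duration_frames
        covered = np.sum(gt.fixation_intervals[:, 1]
                         - gt.fixation_intervals[:, 0])
        total = default_session.t.size / 60.0
        assert covered + gt.saccade_onset_frames.size * d / 60.0 == \
            pytest.approx(total)

    def test_approach_truth_satisfies_criteria_when_rederived(
            self, default_session):
        s = default_session
        ana = analyze_channels(s.channels)
        det = detect_approaches(ana.speed, ana.geometry.azimuth,
                                ana.geometry.range_rate, 60.0,
                                merge_gap=0.0, min_duration=0.0)
        gt = s.ground_truth.approach_intervals
        assert det.intervals.shape == gt.shape
        assert np.max(np.abs(det.intervals - gt)) <= 1.0 / 60.0

    def test_session_scale_statistics(self, default_session):
        """The default session realizes the intended study conditions."""
        gt = default_session.ground_truth
        assert 350 <= gt.saccade_onset_frames.size <= 900
        assert gt.approach_intervals.shape[0] >= 5
        fl = gt.fixation_intervals[:, 1] - gt.fixation_intervals[:, 0]
        assert 0.2 < np.median(fl) < 2.0
        th = default_session.channels["theta_mean"]
        assert np.max(np.abs(th)) < 60.0


class TestProjection:
    def test_on_axis_is_circle_at_center(self):
        (e,), _ = project_pupil(0.0, 0.0, (320, 240), 60.0)
        assert e.center == (320.0, 240.0)
        assert e.ellipticity == pytest.approx(1.0)

    def test_thirty_degrees_closed_form(self):
        (e,), _ = project_pupil(30.0, 0.0, (320, 240), 60.0)
        np.testing.assert_allclose(e.center, (350.0, 240.0))
        assert e.ellipticity == pytest.approx(np.cos(np.deg2rad(30)))
        assert abs(e.phi) == pytest.approx(90.0)    # major axis vertical

    def test_full_loop_recovers_angles(self, rng):
        th = rng.uniform(-30, 30, 400)
        tv = rng.uniform(-30, 30, 400)
        _, pts = project_pupil(th, tv, (320, 240), 60.0)
        cal = calibrate_eye(fit_pupil_ellipses(pts))
        fits = fit_pupil_ellipses(pts)
        ah, av = pupil_to_angle(np.array([e.center for e in fits]), cal)
        assert np.max(np.abs(ah - th)) < 0.2
        assert np.max(np.abs(av - tv)) < 0.2

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            project_pupil(95.0, 0.0)


@pytest.fixture(scope="module")
def exported(tmp_path_factory):
    s = simulate_session(SimulationParams(duration=60.0, seed=7))
    out = tmp_path_factory.mktemp("session")
    paths = export_raw_style(s, out)
    return s, paths


class TestRawExportRoundtrip:

    def test_head_landmarks_refit_recovers_yaw(self, tmp_path):
        s = simulate_session(SimulationParams(duration=30.0, seed=9))
        paths = export_raw_style(s, tmp_path, overhead_noise_cm=0.0)
        lm = load_landmarks(paths["overhead"], frame_rate=30.0)
        names = DEFAULT_HEAD_TEMPLATE.names
        head = LandmarkSeries(lm.timestamps,
                              {k: lm.points[k] for k in names},
                              {k: lm.confidence[k] for k in names}, 30.0)
        poses = fit_head_poses(head, DEFAULT_HEAD_TEMPLATE)
        idx = np.arange(0, s.t.size, 2)
        err = wrap_degrees(poses.yaw - s.channels["yaw"][idx])
        assert np.nanmax(np.abs(err)) < 0.1

    def test_imu_rederived_pitch_matches(self, exported):
        s, paths = exported
        meta = json.load(open(paths["meta"]))
        imu = load_imu(paths["imu"], [meta["accel_gain"]] * 3,
                       [meta["gyro_gain"]] * 3)
        der = process_imu(imu)
        truth = np.interp(imu.timestamps, s.t, s.channels["pitch"])
        assert np.sqrt(np.mean((der.pitch - truth) ** 2)) < 0.5

    def test_eye_files_recalibrate_and_recover_angles(self, exported):
        s, paths = exported
        lm = load_landmarks(paths["eye_right"], frame_rate=60.0)
        pts = np.stack([lm.points[f"pupil_{k}"] for k in range(8)], axis=1)
        ells = fit_pupil_ellipses(pts)
        cal = calibrate_eye(ells, min_eccentricity=0.05,
                            regression="inverse")
        centers = np.array([e.center if e else (np.nan, np.nan)
                            for e in ells])
        th, _ = pupil_to_angle(centers, cal)
        err = th - s.channels["theta_r"]
        assert np.sqrt(np.nanmean(err**2)) < 1.5

    def test_reloaded_speed_matches_session(self, exported):
        s, paths = exported
        lm = load_landmarks(paths["overhead"], frame_rate=30.0)
        names = DEFAULT_HEAD_TEMPLATE.names
        head = LandmarkSeries(lm.timestamps,
                              {k: lm.points[k] for k in names},
                              {k: lm.confidence[k] for k in names}, 30.0)
        poses = fit_head_poses(head, DEFAULT_HEAD_TEMPLATE)
        sp = compute_speed(poses.x, poses.y, 30.0)
        truth = s.channels["speed"][::2]
        # moving/stationary agreement at the 1 cm/s threshold
        agree = np.mean((sp > 1.0) == (truth > 1.0))
        assert agree > 0.95


class TestMeasuredOverlay:
    def test_noise_level_matches_sigma(self, short_session):
        m = short_session.measured()
        resid = m["theta_r"] - short_session.channels["theta_r"]
        assert np.std(resid) == pytest.approx(0.5, rel=0.1)
        assert np.std(m["x"] - short_session.channels["x"]) == pytest.approx(
            0.05, rel=0.15)

    def test_overlay_never_mutates_truth(self, short_session):
        before = short_session.channels["yaw"].copy()
        short_session.measured()
        np.testing.assert_array_equal(short_session.channels["yaw"], before)
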