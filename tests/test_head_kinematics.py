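import numpy as np
import pandas as pd
import pytest

from preygaze.angles import wrap_degrees
from preygaze.exceptions import AnalysisError, FitError
from preygaze.head_kinematics import (HeadPoseSeries, HeadTemplate, ImuAxisMap,
                                      compute_mean_geometry, compute_speed,
                                      estimate_head_measurement_error,
                                      fit_rigid_pose, process_imu,
                                      target_geometry, GRAVITY)
from preygaze.io_timebase import ImuSeries, LandmarkSeries
from preygaze.synthetic import DEFAULT_HEAD_TEMPLATE


def rot(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def brute_force_yaw(frame, template, step=0.01):
    """Dense rotation search minimizing the rigid residual (oracle)."""
    A = template.coords - template.coords.mean(axis=0)
    B = frame - frame.mean(axis=0)
    grid = np.arange(-180.0, 180.0, step)
    s = float(np.sum(A * B))
    c = float(np.sum(A[:, 0] * B[:, 1] - A[:, 1] * B[:, 0]))
    obj = -(s * np.cos(np.deg2rad(grid)) + c * np.sin(np.deg2rad(grid)))
    return grid[np.argmin(obj)]


class TestRigidPose:
    def test_pure_rotation_and_translation(self):
        tmpl = DEFAULT_HEAD_TEMPLATE
        frame = tmpl.coords @ rot(90).T + np.array([5.0, 5.0])
        x, y, yaw, res = fit_rigid_pose(frame, tmpl)
        assert (x, y) == pytest.approx((5.0, 5.0))
        assert yaw == pytest.approx(90.0)
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_single_valid_point_is_invalid_frame(self):
        tmpl = DEFAULT_HEAD_TEMPLATE
        frame = tmpl.coords.copy()
        conf = np.zeros(8)
        conf[0] = 1.0
        x, y, yaw, res = fit_rigid_pose(frame, tmpl, confidence=conf)
        assert np.isnan(yaw)

    def test_matches_brute_force_rotation_search(self, rng):
        tmpl = DEFAULT_HEAD_TEMPLATE
        for _ in range(30):
            ang = rng.uniform(-180, 180)
            frame = (tmpl.coords @ rot(ang).T + rng.uniform(-10, 10, 2)
                     + rng.normal(0, 0.1, (8, 2)))
            _, _, yaw, _ = fit_rigid_pose(frame, tmpl)
            oracle = brute_force_yaw(frame, tmpl)
            assert abs(wrap_degrees(yaw - oracle)) <= 0.01

    def test_invariant_to_global_transform(self, rng):
        tmpl = DEFAULT_HEAD_TEMPLATE
        frame = tmpl.coords @ rot(25).T + [3, 4] + rng.normal(0, 0.1, (8, 2))
        x0, y0, yaw0, res0 = fit_rigid_pose(frame, tmpl)
        g = 40.0
        moved = frame @ rot(g).T + np.array([-2.0, 6.0])
        x1, y1, yaw1, res1 = fit_rigid_pose(moved, tmpl)
        np.testing.assert_allclose([x1, y1],
                                   rot(g) @ np.array([x0, y0]) + [-2, 6],
                                   atol=1e-9)
        assert wrap_degrees(yaw1 - yaw0) == pytest.approx(g, abs=1e-9)
        assert res1 == pytest.approx(res0, abs=1e-9)

    def test_weights_downweight_bad_landmark(self):
        tmpl = DEFAULT_HEAD_TEMPLATE
        frame = tmpl.coords @ rot(10).T
        frame[3] += 50.0                      # gross outlier
        conf = np.ones(8)
        conf[3] = 0.1                         # below threshold -> ignored
        _, _, yaw, res = fit_rigid_pose(frame, tmpl, confidence=conf)
        assert yaw == pytest.approx(10.0, abs=1e-9)


class TestMeanGeometry:
    def _series(self, frames):
        n = len(frames)
        names = DEFAULT_HEAD_TEMPLATE.names
        pts = {nm: np.array([f[i] for f in frames])
               for i, nm in enumerate(names)}
        conf = {nm: np.ones(n) for nm in names}
        return LandmarkSeries(np.arange(n) / 60.0, pts, conf, 60.0)

    def test_rigid_family_recovers_shape(self, rng):
        shape = DEFAULT_HEAD_TEMPLATE.coords
        frames = [shape @ rot(rng.uniform(-180, 180)).T + rng.uniform(-5, 5, 2)
                  for _ in range(20)]
        tmpl = compute_mean_geometry(self._series(frames))
        # template congruent to the true shape: residual of a rigid fit ~ 0
        _, _, _, res = fit_rigid_pose(shape, tmpl)
        assert res < 1e-6

    def test_noisy_frames_average_toward_truth(self, rng):
        shape = DEFAULT_HEAD_TEMPLATE.coords
        sigma, nf = 0.05, 200
        frames = [shape @ rot(rng.uniform(-180, 180)).T
                  + rng.uniform(-5, 5, 2) + rng.normal(0, sigma, shape.shape)
                  for _ in range(nf)]
        tmpl = compute_mean_geometry(self._series(frames))
        _, _, _, res = fit_rigid_pose(shape, tmpl)
        assert res < 4 * sigma / np.sqrt(nf)

    def test_too_few_usable_frames(self):
        shape = DEFAULT_HEAD_TEMPLATE.coords
        series = self._series([shape] * 5)
        with pytest.raises(FitError):
            compute_mean_geometry(series)


class TestSpeed:
    def test_stationary_and_uniform_motion(self):
        n = 120
        assert np.allclose(compute_speed(np.zeros(n), np.zeros(n), 60.0), 0.0)
        x = np.arange(n, dtype=float)  # 1 cm/frame at 60 Hz
        sp = compute_speed(x, np.zeros(n), 60.0)
        np.testing.assert_allclose(sp, 60.0)

    def test_single_frame_glitch_suppressed(self):
        x = np.zeros(240)
        x[100] = 5.0                 # jump and return
        sp = compute_speed(x, np.zeros(240), 60.0)
        assert sp[100] == 0.0


class TestTargetGeometry:
    def _head(self, yaw, n=64):
        return HeadPoseSeries(np.zeros(n), np.zeros(n), np.full(n, yaw),
                              np.zeros(n), np.ones(n, bool))

    def test_cricket_on_head_axis(self):
        geom = target_geometry(self._head(0.0),
                               np.column_stack([np.full(64, 10.0),
                                                np.zeros(64)]), 60.0)
        np.testing.assert_allclose(geom.distance, 10.0)
        np.testing.assert_allclose(geom.azimuth, 0.0, atol=1e-9)

    def test_cricket_right_of_head_is_positive(self):
        # head along +x, cricket at (0, -5): 90 deg to the right
        geom = target_geometry(self._head(0.0),
                               np.column_stack([np.zeros(64),
                                                np.full(64, -5.0)]), 60.0)
        np.testing.assert_allclose(geom.azimuth, 90.0)
        np.testing.assert_allclose(geom.distance, 5.0)

    def test_constant_closing_speed(self):
        n = 240
        x = 12.0 * np.arange(n) / 60.0       # mouse runs at 12 cm/s
        head = HeadPoseSeries(x, np.zeros(n), np.zeros(n), np.zeros(n),
                              np.ones(n, bool))
        cricket = np.column_stack([np.full(n, 100.0), np.zeros(n)])
        geom = target_geometry(head, cricket, 60.0)
        np.testing.assert_allclose(geom.range_rate[20:-20], -12.0, atol=1e-6)


class TestImu:
    def _imu(self, accel, gyro, n=100):
        t = np.arange(n) / 50.0
        return ImuSeries(t, np.tile(accel, (n, 1)), np.tile(gyro, (n, 1)))

    def test_gravity_on_down_axis_is_level(self):
        der = process_imu(self._imu([0, 0, GRAVITY], [0, 0, 0]))
        np.testing.assert_allclose(der.pitch, 0.0)
        np.testing.assert_allclose(der.roll, 0.0)

    def test_forward_gravity_is_ninety_degrees_nose_up(self):
        der = process_imu(self._imu([GRAVITY, 0, 0], [0, 0, 0]))
        np.testing.assert_allclose(der.pitch, 90.0)

    def test_gyro_unit_conversion(self):
        der = process_imu(self._imu([0, 0, GRAVITY], [0, 0, 0.5]))
        np.testing.assert_allclose(der.yaw_rate, np.degrees(0.5))

    def test_super_gravity_clipped_and_flagged(self):
        der = process_imu(self._imu([1.2 * GRAVITY, 0, 0], [0, 0, 0]))
        assert der.clipped.all()
        np.testing.assert_allclose(der.pitch, 90.0)

    def test_axis_map_sign(self):
        amap = ImuAxisMap(forward=(0, -1))
        der = process_imu(self._imu([GRAVITY, 0, 0], [0, 0, 0]), amap)
        np.testing.assert_allclose(der.pitch, -90.0)


class TestHeadMeasurementError:
    def test_identical_estimates_give_zero(self):
        yaw = np.cumsum(np.full(200, 0.5))
        rate_imu = np.full(200, 0.5 * 60.0)
        assert estimate_head_measurement_error(rate_imu, yaw, 60.0) == 0.0

    def test_iid_noise_gives_sigma_sqrt_two(self, rng):
        n = 200_000
        sigma = 0.3
        true = np.cumsum(rng.normal(0, 1.0, n))
        yaw_lm = true + rng.normal(0, sigma, n)
        imu_rate = np.diff(true, prepend=true[0]) * 60.0
        imu_rate = np.roll(imu_rate, -1)     # rate over frame i -> i+1
        est = estimate_head_measurement_error(imu_rate, yaw_lm, 60.0)
        assert est == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_empty_overlap_errors(self):
        with pytest.raises(AnalysisError):
            estimate_head_measurement_error(np.full(5, np.nan),
                                            np.full(5, np.nan), 60.0)
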