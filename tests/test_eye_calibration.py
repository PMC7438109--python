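import numpy as np
import pytest

from preygaze.exceptions import AnalysisError, CalibrationError, FitError
from preygaze.eye_calibration import (CameraCalibration, Ellipse, calibrate_eye,
                                      center_eye_positions,
                                      estimate_camera_center,
                                      estimate_eye_measurement_error,
                                      estimate_scale, EyeAngleSeries,
                                      fit_pupil_ellipse, fit_pupil_ellipses,
                                      pupil_to_angle)
from preygaze.synthetic import project_pupil


def parametric_points(center, a, b, phi_deg, n=8):
    psi = 2 * np.pi * np.arange(n) / n
    phi = np.deg2rad(phi_deg)
    major = np.array([np.cos(phi), np.sin(phi)])
    minor = np.array([-np.sin(phi), np.cos(phi)])
    return (np.asarray(center)
            + a * np.cos(psi)[:, None] * major
            + b * np.sin(psi)[:, None] * minor)


class TestEllipseFit:
    def test_circle_recovered(self):
        pts = parametric_points((100, 100), 10, 10, 0)
        e = fit_pupil_ellipse(pts)
        np.testing.assert_allclose(e.center, (100, 100), atol=1e-8)
        np.testing.assert_allclose([e.a, e.b], 10, atol=1e-8)
        assert e.ellipticity == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["direct", "taubin"])
    @pytest.mark.parametrize("phi", [-60.0, 0.0, 30.0, 85.0])
    def test_parametric_recovery(self, method, phi):
        pts = parametric_points((50, 40), 10, 6, phi)
        e = fit_pupil_ellipse(pts, method=method)
        np.testing.assert_allclose(e.center, (50, 40), atol=1e-6)
        assert e.a == pytest.approx(10, abs=1e-6)
        assert e.b == pytest.approx(6, abs=1e-6)
        assert e.phi == pytest.approx(phi, abs=1e-6)

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(FitError):
            fit_pupil_ellipse(pts)

    def test_too_few_valid_points_raise(self):
        pts = parametric_points((0, 0), 10, 6, 0)
        conf = np.array([1, 1, 1, 1, 0, 0, 0, 0.0])
        with pytest.raises(FitError):
            fit_pupil_ellipse(pts, confidence=conf)

    def test_equivariant_under_rotation_and_translation(self, rng):
        pts = parametric_points((0, 0), 12, 7, 20, n=8)
        ang = np.deg2rad(37.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ R.T + np.array([5.0, -3.0])
        e0 = fit_pupil_ellipse(pts)
        e1 = fit_pupil_ellipse(moved)
        np.testing.assert_allclose(e1.center,
                                   R @ np.array(e0.center) + [5, -3], atol=1e-6)
        assert e1.a == pytest.approx(e0.a, abs=1e-6)
        assert e1.phi == pytest.approx(e0.phi + 37.0, abs=1e-6)

    def test_matches_independent_skimage_fit(self, rng):
        """Cross-check against scikit-image's ellipse model on noisy points."""
        from skimage.measure import EllipseModel
        for _ in range(20):
            a, b = sorted(rng.uniform(5, 15, 2))[::-1]
            pts = parametric_points(rng.uniform(-50, 50, 2), a, max(b, 1.0),
                                    rng.uniform(-80, 80))
            pts = pts + rng.normal(0, 0.05, pts.shape)
            ours = fit_pupil_ellipse(pts, method="direct")
            m = EllipseModel()
            assert m.estimate(pts)
            xc, yc, sa, sb, _ = m.params
            np.testing.assert_allclose(ours.center, (xc, yc), atol=1e-3)
            np.testing.assert_allclose(sorted([ours.a, ours.b]),
                                       sorted([sa, sb]), rtol=1e-3)


class TestCameraCenter:
    def test_two_orthogonal_major_axes_intersect_exactly(self):
        # major axis perpendicular to (p - c); c = (10, 20)
        e1 = Ellipse((40, 20), 10, 8, 90.0)   # p right of c -> vertical axis
        e2 = Ellipse((10, 55), 10, 8, 0.0)    # p above c -> horizontal axis
        c = estimate_camera_center([e1, e2])
        np.testing.assert_allclose(c, (10, 20), atol=1e-9)

    def test_noiseless_projection_recovered(self, rng):
        th = rng.uniform(-30, 30, 20)
        tv = rng.uniform(-30, 30, 20)
        ells, _ = project_pupil(th, tv, (320, 240), 60.0)
        c = estimate_camera_center(ells)
        np.testing.assert_allclose(c, (320, 240), atol=1e-6)

    def test_all_near_circular_frames_rejected(self):
        ells = [Ellipse((100 + i, 100), 10, 9.99, float(i)) for i in range(10)]
        with pytest.raises(CalibrationError):
            estimate_camera_center(ells, min_eccentricity=0.01)

    def test_parallel_axes_ill_conditioned(self):
        ells = [Ellipse((100, 100 + i), 10, 8, 0.0) for i in range(10)]
        with pytest.raises(CalibrationError):
            estimate_camera_center(ells)


class TestScale:
    def test_single_frame_closed_form(self):
        e = Ellipse((130, 100), 10, 10 * np.cos(np.deg2rad(30)), 90.0)
        # |p - c| = 30 px, e = cos(30) -> R = 30 / sin(30) = 60
        assert estimate_scale([e], (100, 100)) == pytest.approx(60.0)

    def test_circular_frames_only_error(self):
        ells = [Ellipse((100, 100), 10, 10, 0.0)] * 5
        with pytest.raises(CalibrationError):
            estimate_scale(ells, (90, 100))

    def test_noiseless_multiframe_recovery(self, rng):
        th = rng.uniform(-30, 30, 50)
        ells, _ = project_pupil(th, np.zeros(50) + 10.0, (320, 240), 60.0)
        c = estimate_camera_center(ells)
        for reg in ("slope", "inverse"):
            assert estimate_scale(ells, c, regression=reg) == pytest.approx(
                60.0, rel=1e-6)

    def test_invariant_to_joint_translation(self, rng):
        th = rng.uniform(-30, 30, 30)
        ells, _ = project_pupil(th, np.full(30, 12.0), (320, 240), 60.0)
        shifted = [Ellipse((e.center[0] + 7, e.center[1] - 4), e.a, e.b, e.phi)
                   for e in ells]
        r0 = estimate_scale(ells, (320, 240))
        r1 = estimate_scale(shifted, (327, 236))
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestPupilToAngle:
    def setup_method(self):
        self.cal = CameraCalibration((320, 240), 60.0)

    def test_on_axis_is_zero(self):
        assert pupil_to_angle((320, 240), self.cal) == pytest.approx((0, 0))

    def test_half_radius_is_thirty_degrees(self):
        th, tv = pupil_to_angle((350, 240), self.cal)
        assert th == pytest.approx(30.0)
        assert tv == pytest.approx(0.0)

    def test_sign_map_flips_horizontal(self):
        th, _ = pupil_to_angle((350, 240), self.cal, sign_h=-1)
        assert th == pytest.approx(-30.0)

    def test_outside_sphere_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            th, _ = pupil_to_angle((320 + 61, 240), self.cal)
        assert th == pytest.approx(90.0)

    def test_roundtrip_through_projection_model(self):
        g = np.linspace(-30, 30, 13)
        th, tv = np.meshgrid(g, g)
        th, tv = th.ravel(), tv.ravel()
        ells, pts = project_pupil(th, tv, (320, 240), 60.0)
        fits = fit_pupil_ellipses(pts)
        cal = calibrate_eye(fits)
        ah, av = pupil_to_angle(np.array([e.center for e in fits]), cal)
        assert np.max(np.abs(ah - th)) < 0.2
        assert np.max(np.abs(av - tv)) < 0.2


class TestCentering:
    def test_constant_trace_becomes_zero(self):
        s = EyeAngleSeries(np.full(10, 7.0), np.zeros(10), np.ones(10, bool))
        out = center_eye_positions(s)
        np.testing.assert_allclose(out.theta_h, 0.0)

    def test_output_mean_is_zero(self, rng):
        s = EyeAngleSeries(rng.normal(3, 2, 500), rng.normal(-1, 2, 500),
                           np.ones(500, bool))
        out = center_eye_positions(s)
        assert abs(out.theta_h.mean()) < 1e-12
        assert abs(out.theta_v.mean()) < 1e-12

    def test_masked_samples_excluded_from_mean(self):
        th = np.array([1.0, 1.0, 100.0])
        valid = np.array([True, True, False])
        out = center_eye_positions(EyeAngleSeries(th, th, valid))
        np.testing.assert_allclose(out.theta_h[:2], 0.0)

    def test_all_invalid_errors(self):
        s = EyeAngleSeries(np.ones(3), np.ones(3), np.zeros(3, bool))
        with pytest.raises(AnalysisError):
            center_eye_positions(s)


class TestMeasurementError:
    def test_constant_trace_gives_zero(self):
        n = 100
        assert estimate_eye_measurement_error(
            np.full(n, 2.0), np.zeros(n), np.zeros(n)) == 0.0

    def test_iid_noise_recovered_within_five_percent(self, rng):
        n = 200_000
        sigma = 0.7
        theta = rng.normal(0, sigma, n)
        est = estimate_eye_measurement_error(theta, np.zeros(n), np.zeros(n))
        assert est == pytest.approx(sigma, rel=0.05)

    def test_window_method_agrees_for_iid_noise(self, rng):
        n = 100_000
        theta = rng.normal(0, 0.5, n)
        est = estimate_eye_measurement_error(theta, np.zeros(n), np.zeros(n),
                                             method="window_std")
        assert est == pytest.approx(0.5, rel=0.05)

    def test_no_stationary_samples_errors(self):
        n = 50
        with pytest.raises(AnalysisError):
            estimate_eye_measurement_error(np.ones(n), np.full(n, 10.0),
                                           np.zeros(n))

    def test_moving_samples_excluded(self, rng):
        n = 50_000
        theta = rng.normal(0, 0.3, n)
        speed = np.zeros(n)
        speed[: n // 2] = 5.0       # first half is moving
        theta[: n // 2] += 50.0     # gross artifacts on moving samples
        est = estimate_eye_measurement_error(theta, speed, np.zeros(n))
        assert est == pytest.approx(0.3, rel=0.1)
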