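"""Synthetic prey-capture sessions with ground truth.

Generates sessions carrying the statistical structure the analysis assumes,
so every stage of the pipeline can be verified without recorded data:

* a mouse exploring a 45 x 38 cm arena in move/pause bouts, reorienting with
  discrete head-turn bouts (raised-cosine yaw-velocity pulses), and
  launching pursuit bouts that steer the head onto a cricket until within
  capture distance, after which the cricket relocates;
* head pitch as a mean-reverting process whose variance drops during
  approach (vertical head stabilization);
* VOR-compensated eyes: the mean horizontal eye angle integrates
  -gain * delta(yaw) between saccades and linearly recenters over a couple
  of frames whenever its eccentricity passes a trigger threshold, with a
  refractory period — producing the saccade-and-fixate gaze pattern;
* pitch-coupled vergence V = slope * pitch + noise, split across the two
  eyes as theta_R = theta_mean + V/2, theta_L = theta_mean - V/2;
* forward-projected pupil ellipses (spherical-eye model) for calibration
  tests, and raw-style landmark/IMU file export so the full pipeline runs
  end-to-end from files.

The in-memory session channels are noiseless ground truth; measurement
noise is an overlay, applied when channels are read out through
:meth:`SyntheticSession.measured` or when raw-style files are written.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .angles import wrap_degrees
from .eye_calibration import Ellipse
from .epochs import detect_approaches, detect_moving, intervals_from_mask
from .head_kinematics import (GRAVITY, HeadPoseSeries, HeadTemplate,
                              compute_speed, target_geometry)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SyntheticSession",
    "DEFAULT_HEAD_TEMPLATE",
    "simulate_session",
    "project_pupil",
    "export_raw_style",
]

# mean head geometry used for rendering overhead landmarks (cm, centroid at
# origin, nose-to-head_center line along +x so yaw reference angle is 0)
_TEMPLATE_POINTS = {
    "nose": (2.5, 0.0),
    "head_center": (0.0, 0.0),
    "led_l": (0.6, 0.9),
    "led_r": (0.6, -0.9),
    "conn_l": (-0.3, 0.6),
    "conn_r": (-0.3, -0.6),
    "ear_l": (-0.8, 1.1),
    "ear_r": (-0.8, -1.1),
}


def _make_template() -> HeadTemplate:
    names = list(_TEMPLATE_POINTS)
    coords = np.array([_TEMPLATE_POINTS[nm] for nm in names], dtype=float)
    coords -= coords.mean(axis=0)
    return HeadTemplate(names, coords)


DEFAULT_HEAD_TEMPLATE = _make_template()


@dataclass
class SimulationParams:
    """Study conditions for one synthetic session.

    Oculomotor defaults (VOR gain 1, 15 deg trigger eccentricity, 2-frame
    saccades, pitch-vergence slope -0.5, 0.5 deg measurement noise) and the
    arena are the conditions the analysis is designed around; behavioral
    bout parameters are generator design choices documented in the methods
    note.
    """

    # session
    arena: tuple[float, float] = (45.0, 38.0)   # cm (x, y extent)
    duration: float = 600.0                      # s
    rate: float = 60.0                           # Hz
    seed: int = 0
    # oculomotor
    vor_gain: float = 1.0
    saccade_trigger_deg: float = 15.0
    saccade_duration_frames: int = 2
    saccade_refractory_frames: int = 3
    # pitch / vergence
    pitch_vergence_slope: float = -0.5           # deg vergence per deg pitch
    pitch_period_s: float = 3.0                  # quasi-period of pitch sway
    pitch_sigma_explore: float = 10.0            # deg, stationary std
    pitch_sigma_approach: float = 3.0
    vergence_noise_sigma: float = 0.8            # deg, OU std
    vertical_eye_sigma: float = 5.0              # deg, OU std
    vertical_eye_tau: float = 0.4
    # locomotion
    explore_speed: float = 8.0                   # cm/s target while moving
    approach_speed: float = 30.0
    speed_tau: float = 0.3
    pause_mean_s: float = 1.6
    move_mean_s: float = 2.2
    approach_rate_hz: float = 0.25               # approach starts per moving s
    capture_distance: float = 2.5                # cm
    cricket_relocation_rate: float = 0.02        # spontaneous, per s
    cricket_flee_speed: float = 12.0             # cm/s when mouse closes in
    cricket_flee_radius: float = 10.0            # cm
    # head-turn bouts
    turn_gap_mean_s: float = 0.55                # explore, mean extra gap
    turn_gap_min_s: float = 0.25                 # explore, minimum gap
    turn_amp_sigma: float = 16.0                 # deg, explore bout amplitude
    turn_amp_max: float = 30.0                   # deg, single-bout cap
    turn_duration_s: float = 0.25
    turn_peak_rate: float = 350.0                # deg/s cap on bout velocity
    approach_adjust_gap_s: float = 0.4
    turn_noise_sigma: float = 6.0                # deg/s between bouts
    # measurement-noise overlay (exported channels only)
    sigma_meas: float = 0.5                      # deg, angle channels
    sigma_pos: float = 0.05                      # cm, position channels
    # eye-camera projection
    camera_center: tuple[float, float] = (320.0, 240.0)   # px
    camera_scale: float = 60.0                            # R, px
    pupil_radius_px: float = 28.0

    def validate(self):
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.vor_gain < 0 or self.sigma_meas < 0 or self.sigma_pos < 0:
            raise ValueError("gain and noise levels must be non-negative")
        if self.saccade_duration_frames < 1:
            raise ValueError("saccade duration must be >=1 frame")
        return self


@dataclass
class GroundTruth:
    """Event log and noiseless references for recovery tests."""

    saccade_onset_frames: np.ndarray
    saccade_onsets_s: np.ndarray
    saccade_amplitudes: np.ndarray       # true delta-gaze across each reset
    fixation_intervals: np.ndarray       # (m, 2) s, half-open
    approach_intervals: np.ndarray       # (m, 2) s
    moving_intervals: np.ndarray
    calibration: dict = field(default_factory=dict)   # per-eye truth (c, R)
    pitch_vergence_slope: float = -0.5
    vor_gain: float = 1.0

    def to_json(self, path=None) -> str:
        doc = {
            "saccade_onset_frames": np.asarray(self.saccade_onset_frames).tolist(),
            "saccade_onsets_s": np.asarray(self.saccade_onsets_s).tolist(),
            "saccade_amplitudes": np.asarray(self.saccade_amplitudes).tolist(),
            "fixation_intervals": np.asarray(self.fixation_intervals).tolist(),
            "approach_intervals": np.asarray(self.approach_intervals).tolist(),
            "moving_intervals": np.asarray(self.moving_intervals).tolist(),
            "calibration": self.calibration,
            "pitch_vergence_slope": self.pitch_vergence_slope,
            "vor_gain": self.vor_gain,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SyntheticSession:
    """One generated session: noiseless channels + ground truth."""

    params: SimulationParams
    t: np.ndarray
    channels: dict[str, np.ndarray]      # noiseless; yaw/gaze unwrapped
    ground_truth: GroundTruth
    head_template: HeadTemplate
    _noise_seed: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, **self.channels})

    def measured(self, seed: int | None = None) -> dict[str, np.ndarray]:
        """Channels with the measurement-noise overlay applied.

        iid Gaussian noise of ``sigma_meas`` deg on angle channels and
        ``sigma_pos`` cm on positions; deterministic for the session's seed
        unless an explicit one is given.
        """
        rng = np.random.default_rng(self._noise_seed if seed is None else seed)
        p = self.params
        out = {}
        for name, arr in self.channels.items():
            if name in ("yaw", "pitch", "roll", "theta_r", "theta_l",
                        "theta_v_r", "theta_v_l"):
                out[name] = arr + rng.normal(0.0, p.sigma_meas, arr.shape)
            elif name in ("x", "y", "cricket_x", "cricket_y"):
                out[name] = arr + rng.normal(0.0, p.sigma_pos, arr.shape)
            else:
                out[name] = arr.copy()
        return out


class _OU:
    """Mean-reverting process stepped at dt with a settable stationary std."""

    def __init__(self, tau, sigma_st, rng, x0=0.0):
        self.tau, self.rng, self.x = tau, rng, x0
        self.sigma_st = sigma_st

    def step(self, dt, sigma_st=None, mean=0.0):
        if sigma_st is not None:
            self.sigma_st = sigma_st
        a = np.exp(-dt / self.tau)
        noise = self.sigma_st * np.sqrt(max(0.0, 1.0 - a * a))
        self.x = mean + (self.x - mean) * a + noise * self.rng.standard_normal()
        return self.x


class _Smooth2:
    """Critically damped noise-driven oscillator: a smooth (C^1) stationary
    process, so short median filters track it closely (unlike a raw OU path,
    whose roughness defeats them)."""

    def __init__(self, period_s, sigma_st, rng):
        self.omega = 2.0 * np.pi / period_s
        self.rng = rng
        self.sigma_st = sigma_st
        self.p = 0.0
        self.v = 0.0

    def step(self, dt, sigma_st=None):
        if sigma_st is not None:
            self.sigma_st = sigma_st
        drive = np.sqrt(4.0 * self.omega**3) * self.sigma_st
        self.v += dt * (-2.0 * self.omega * self.v - self.omega**2 * self.p)
        self.v += drive * np.sqrt(dt) * self.rng.standard_normal()
        self.p += dt * self.v
        return self.p


def _cos_pulse(amplitude: float, duration_frames: int) -> np.ndarray:
    """Raised-cosine angular-velocity pulse integrating to ``amplitude``."""
    k = max(int(duration_frames), 1)
    ph = (np.arange(k) + 0.5) / k
    prof = 1.0 - np.cos(2.0 * np.pi * ph)
    return amplitude * prof / prof.sum()


_PAUSE, _MOVE, _APPROACH = 0, 1, 2


def simulate_session(params: SimulationParams | None = None) -> SyntheticSession:
    """Generate one session. Deterministic given ``params.seed``."""
    p = (params or SimulationParams()).validate()
    ss = np.random.SeedSequence(p.seed)
    s_behav, s_eyes, s_noise = ss.spawn(3)
    rng = np.random.default_rng(s_behav)
    eye_rng = np.random.default_rng(s_eyes)

    rate, dt = p.rate, 1.0 / p.rate
    n = int(round(p.duration * rate))
    W, H = p.arena
    margin = 4.0

    # --- behavioral trajectory -------------------------------------------
    x = np.empty(n); y = np.empty(n); yaw = np.empty(n)
    speed_cmd = np.empty(n); state = np.empty(n, dtype=int)
    pitch = np.empty(n); roll = np.empty(n)
    bout_active = np.zeros(n, dtype=bool)

    pos = np.array([W / 2.0, H / 2.0])
    heading = float(rng.uniform(-180.0, 180.0))
    cricket = np.empty((n, 2))
    ck = np.array([rng.uniform(margin, W - margin),
                   rng.uniform(margin, H - margin)])

    spd = _OU(p.speed_tau, 1.5, rng, x0=p.explore_speed)
    pitch_ou = _Smooth2(p.pitch_period_s, p.pitch_sigma_explore, rng)
    roll_ou = _Smooth2(p.pitch_period_s, 3.0, rng)
    turn_noise = _OU(0.15, p.turn_noise_sigma, rng)

    mode = _MOVE
    mode_timer = rng.exponential(p.move_mean_s)
    pulse = np.empty(0)       # pending per-frame yaw increments of a bout
    pulse_i = 0
    next_bout = p.turn_gap_min_s + rng.exponential(p.turn_gap_mean_s)
    wall_cooldown = 0.0
    flee_bias = 0.0

    # oculomotor state (updated in the same loop: saccade onset truncates
    # the ongoing turn bout, coupling saccades to head-turn completion)
    theta_mean = np.zeros(n)
    onsets: list[int] = []
    in_sacc = 0
    sacc_step = 0.0
    refractory = 0
    d = p.saccade_duration_frames

    def start_bout(amplitude, cap=None, peak=None):
        # duration grows with amplitude so the raised-cosine peak velocity
        # (2 * amp / dur) stays below the peak-rate cap; single bouts are
        # capped — larger reorientations happen as successive bouts
        nonlocal pulse, pulse_i
        cap = p.turn_amp_max if cap is None else cap
        peak = p.turn_peak_rate if peak is None else peak
        amplitude = float(np.clip(amplitude, -cap, cap))
        dur_s = max(p.turn_duration_s, 2.0 * abs(amplitude) / peak)
        pulse = _cos_pulse(amplitude, max(int(round(dur_s * rate)), 2))
        pulse_i = 0

    def azimuth_error():
        bearing = np.degrees(np.arctan2(ck[1] - pos[1], ck[0] - pos[0]))
        return wrap_degrees(heading - bearing)

    for i in range(n):
        # mode transitions
        mode_timer -= dt
        if mode == _APPROACH:
            if np.hypot(*(ck - pos)) < p.capture_distance:
                ck = np.array([rng.uniform(margin, W - margin),
                               rng.uniform(margin, H - margin)])
                mode, mode_timer = _MOVE, rng.exponential(p.move_mean_s)
                pulse = np.empty(0)
            elif mode_timer <= 0:   # failed pursuit, give up
                mode, mode_timer = _MOVE, rng.exponential(p.move_mean_s)
                pulse = np.empty(0)
        elif mode == _MOVE:
            if mode_timer <= 0:
                mode, mode_timer = _PAUSE, rng.exponential(p.pause_mean_s)
            elif (np.hypot(*(ck - pos)) > 8.0
                  and rng.random() < p.approach_rate_hz * dt):
                mode, mode_timer = _APPROACH, 6.0
                # single large orienting turn onto the cricket; the cricket
                # escapes on a curved path whose side is fixed per chase
                flee_bias = float(rng.choice([-1.0, 1.0]) * rng.uniform(35.0, 60.0))
                start_bout(-azimuth_error(), cap=120.0)
                next_bout = p.approach_adjust_gap_s
        else:  # PAUSE
            if mode_timer <= 0:
                mode, mode_timer = _MOVE, rng.exponential(p.move_mean_s)
                next_bout = p.turn_gap_min_s + rng.exponential(p.turn_gap_mean_s)
        if mode != _APPROACH and rng.random() < p.cricket_relocation_rate * dt:
            ck = np.array([rng.uniform(margin, W - margin),
                           rng.uniform(margin, H - margin)])
        # cricket flees a closing mouse (prolongs the chase)
        if mode == _APPROACH and np.hypot(*(ck - pos)) < p.cricket_flee_radius:
            flee = np.degrees(np.arctan2(ck[1] - pos[1], ck[0] - pos[0]))
            flee += flee_bias + 15.0 * rng.standard_normal()
            ck = ck + p.cricket_flee_speed * dt * np.array(
                [np.cos(np.deg2rad(flee)), np.sin(np.deg2rad(flee))])
            ck = np.clip(ck, margin, [W - margin, H - margin])

        # head-turn bouts
        dyaw = 0.0
        if pulse_i < pulse.size:
            dyaw += pulse[pulse_i]
            pulse_i += 1
            bout_active[i] = True
        else:
            next_bout -= dt
            if next_bout <= 0:
                if mode == _MOVE:
                    start_bout(rng.normal(0.0, p.turn_amp_sigma))
                    next_bout = p.turn_gap_min_s + rng.exponential(p.turn_gap_mean_s)
                elif mode == _APPROACH:
                    # tracking corrections are slower than orienting turns
                    start_bout(-azimuth_error() + rng.normal(0.0, 3.0),
                               cap=45.0, peak=250.0)
                    next_bout = p.approach_adjust_gap_s
                else:
                    next_bout = rng.exponential(p.turn_gap_mean_s)
        if mode != _PAUSE:
            dyaw += turn_noise.step(dt) * dt
        # steer away from walls (with a cooldown so bouts stay discrete)
        wall_cooldown = max(wall_cooldown - dt, 0.0)
        if mode != _PAUSE and wall_cooldown == 0.0:
            near = (pos[0] < margin or pos[0] > W - margin
                    or pos[1] < margin or pos[1] > H - margin)
            if near and pulse_i >= pulse.size:
                to_center = np.degrees(np.arctan2(H / 2 - pos[1],
                                                  W / 2 - pos[0]))
                err = wrap_degrees(heading - to_center)
                if abs(err) > 60.0:     # only correct outward headings
                    start_bout(-0.7 * err)
                    wall_cooldown = 0.8
        heading = heading + dyaw   # kept unwrapped

        # VOR-compensated mean eye angle with recentering saccades
        if i > 0:
            if in_sacc > 0:
                theta_mean[i] = theta_mean[i - 1] - sacc_step
                in_sacc -= 1
                if in_sacc == 0:
                    refractory = p.saccade_refractory_frames
            else:
                theta_mean[i] = theta_mean[i - 1] - p.vor_gain * dyaw
                if refractory > 0:
                    refractory -= 1
                # the trigger is gated off during a turn bout, except for
                # mid-turn catch-ups at 2.5x the trigger eccentricity
                elif (np.isfinite(p.saccade_trigger_deg)
                      and (not bout_active[i]
                           or abs(theta_mean[i]) > 2.5 * p.saccade_trigger_deg)
                      and abs(theta_mean[i]) > p.saccade_trigger_deg
                      and i + 1 < n):
                    onsets.append(i + 1)
                    sacc_step = theta_mean[i] / d
                    in_sacc = d
                    # head turns complete with the saccade: a mid-turn
                    # catch-up truncates its bout, and the next bout is
                    # held briefly after any saccade
                    if bout_active[i]:
                        pulse = np.empty(0)
                    next_bout = max(next_bout, 0.3)
                    wall_cooldown = max(wall_cooldown, 0.3)

        # locomotion
        if mode == _APPROACH:
            # full-speed chase, braking only at contact range
            dck = np.hypot(*(ck - pos))
            target = p.approach_speed if dck > 4.0 else max(8.0, 3.0 * dck)
        else:
            target = 0.1 if mode == _PAUSE else p.explore_speed
        v = max(spd.step(dt, sigma_st=0.25 if mode == _PAUSE else 1.5,
                         mean=target), 0.0)
        pos = pos + v * dt * np.array([np.cos(np.deg2rad(heading)),
                                       np.sin(np.deg2rad(heading))])
        pos = np.clip(pos, 1.0, [W - 1.0, H - 1.0])

        sig = p.pitch_sigma_approach if mode == _APPROACH else p.pitch_sigma_explore
        x[i], y[i], yaw[i] = pos[0], pos[1], heading
        pitch[i] = pitch_ou.step(dt, sigma_st=sig)
        roll[i] = roll_ou.step(dt)
        speed_cmd[i] = v
        state[i] = mode
        cricket[i] = ck

    # --- oculomotor channels ---------------------------------------------
    verg_noise = _OU(0.3, p.vergence_noise_sigma, eye_rng)
    theta_v_ou = _OU(p.vertical_eye_tau, p.vertical_eye_sigma, eye_rng)
    vergence = np.empty(n); theta_v = np.empty(n)
    for i in range(n):
        vergence[i] = p.pitch_vergence_slope * pitch[i] + verg_noise.step(dt)
        theta_v[i] = theta_v_ou.step(dt)

    gaze = yaw + theta_mean
    onset_arr = np.array(onsets, dtype=int)
    # true gaze shift across each reset (head keeps moving during the reset)
    amps = []
    for o in onset_arr:
        e = min(o + d - 1, n - 1)
        amps.append(gaze[e] - gaze[o - 1])
    theta_r = theta_mean + vergence / 2.0
    theta_l = theta_mean - vergence / 2.0

    # --- ground-truth events ----------------------------------------------
    sacc_mask = np.zeros(n, dtype=bool)
    for o in onset_arr:
        sacc_mask[o: o + d] = True
    fix_iv = intervals_from_mask(~sacc_mask, rate)

    # operational approach/moving truth: the epoch criteria applied to the
    # noiseless channels through the standard derivation pipeline
    speed_true = compute_speed(x, y, rate)
    pose = HeadPoseSeries(x, y, wrap_degrees(yaw), np.zeros(n),
                          np.ones(n, dtype=bool))
    geom = target_geometry(pose, cricket, rate)
    approach_iv = detect_approaches(speed_true, geom.azimuth, geom.range_rate,
                                    rate, merge_gap=0.0, min_duration=0.0
                                    ).intervals
    moving_iv = detect_moving(speed_true, rate).intervals

    truth = GroundTruth(
        saccade_onset_frames=onset_arr,
        saccade_onsets_s=onset_arr / rate,
        saccade_amplitudes=np.array(amps),
        fixation_intervals=fix_iv,
        approach_intervals=approach_iv,
        moving_intervals=moving_iv,
        calibration={
            "right": {"center": list(p.camera_center), "scale": p.camera_scale},
            "left": {"center": list(p.camera_center), "scale": p.camera_scale},
        },
        pitch_vergence_slope=p.pitch_vergence_slope,
        vor_gain=p.vor_gain,
    )

    channels = {
        "x": x, "y": y, "yaw": yaw, "pitch": pitch, "roll": roll,
        "theta_r": theta_r, "theta_l": theta_l,
        "theta_v_r": theta_v.copy(), "theta_v_l": theta_v.copy(),
        "theta_mean": theta_mean, "vergence": vergence, "gaze": gaze,
        "cricket_x": cricket[:, 0], "cricket_y": cricket[:, 1],
        "speed": speed_true, "distance": geom.distance,
        "azimuth": geom.azimuth, "range_rate": geom.range_rate,
        "state": state.astype(float),
    }
    return SyntheticSession(p, np.arange(n) / rate, channels, truth,
                            DEFAULT_HEAD_TEMPLATE,
                            _noise_seed=int(s_noise.generate_state(1)[0] % (2**31)))


# ---------------------------------------------------------------------------
# Forward pupil projection and raw-style export
# ---------------------------------------------------------------------------

def project_pupil(theta_h, theta_v, center=(320.0, 240.0), scale: float = 60.0,
                  pupil_radius_px: float = 28.0, n_edge_points: int = 8,
                  pixel_noise: float = 0.0, rng=None):
    """Forward-project eye angles to pupil ellipses (+ edge points).

    Spherical-eye model: ellipse center = c + R*(sin th_h, sin th_v);
    ellipticity = cos of the total off-axis angle, i.e.
    sqrt(1 - sin^2 th_h - sin^2 th_v); the major axis is perpendicular to
    the displacement from the camera-axis center. Returns
    ``(ellipses, edge_points)`` with edge points of shape (n, k, 2).
    """
    th = np.atleast_1d(np.asarray(theta_h, dtype=float))
    tv = np.atleast_1d(np.asarray(theta_v, dtype=float))
    if np.nanmax(np.abs(th), initial=0) >= 90 or np.nanmax(np.abs(tv), initial=0) >= 90:
        raise ValueError("|theta| must be < 90 deg")
    center = np.asarray(center, dtype=float)
    rng = rng or np.random.default_rng(0)
    sh, sv = np.sin(np.deg2rad(th)), np.sin(np.deg2rad(tv))
    e = np.sqrt(np.clip(1.0 - sh**2 - sv**2, 1e-12, 1.0))
    cx = center[0] + scale * sh
    cy = center[1] + scale * sv
    psi = 2.0 * np.pi * np.arange(n_edge_points) / n_edge_points
    ellipses: list[Ellipse] = []
    pts = np.empty((th.size, n_edge_points, 2))
    for i in range(th.size):
        u = np.array([sh[i], sv[i]])
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            major = np.array([1.0, 0.0])      # circle: orientation arbitrary
        else:
            major = np.array([-u[1], u[0]]) / norm
        minor = np.array([major[1], -major[0]])
        a = pupil_radius_px
        b = float(e[i]) * a
        phi = float(np.rad2deg(np.arctan2(major[1], major[0])))
        if phi <= -90.0:
            phi += 180.0
        elif phi > 90.0:
            phi -= 180.0
        ellipses.append(Ellipse((float(cx[i]), float(cy[i])), a, b, phi))
        c = np.array([cx[i], cy[i]])
        pts[i] = (c[None, :]
                  + a * np.cos(psi)[:, None] * major[None, :]
                  + b * np.sin(psi)[:, None] * minor[None, :])
    if pixel_noise > 0:
        pts = pts + rng.normal(0.0, pixel_noise, pts.shape)
    return ellipses, pts


def _write_tracker_csv(path, timestamps, frame_rate, bodyparts, coords,
                       likelihood=0.99):
    """coords: dict name -> (n, 2). Three-header-row tracker dialect."""
    n = timestamps.size
    cols = {}
    for bp in bodyparts:
        xy = coords[bp]
        cols[("synthetic", bp, "x")] = xy[:, 0]
        cols[("synthetic", bp, "y")] = xy[:, 1]
        cols[("synthetic", bp, "likelihood")] = np.full(n, likelihood)
    df = pd.DataFrame(cols, index=np.round(timestamps * frame_rate).astype(int))
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["scorer", "bodyparts", "coords"])
    df.to_csv(path)


def export_raw_style(session: SyntheticSession, out_dir,
                     overhead_rate: float = 30.0, imu_rate: float = 50.0,
                     accel_gain: float = 5.0, gyro_gain: float = 10.0,
                     overhead_noise_cm: float = 0.03):
    """Write the raw-style file bundle for one session.

    * ``overhead.csv`` — head + cricket landmarks at the overhead camera
      rate (tracker CSV dialect, cm units);
    * ``eye_right.csv`` / ``eye_left.csv`` — 8 projected pupil-edge points
      per frame at the session rate, pixel noise matched to ``sigma_meas``
      (R * sin(sigma) px);
    * ``imu.csv`` — accelerometer/gyroscope voltages at 50 Hz
      (unit-per-volt gains recorded in ``session_meta.json``);
    * ``ground_truth.json`` + ``session_meta.json``.

    Returns a dict of the written paths.
    """
    import os
    os.makedirs(out_dir, exist_ok=True)
    p = session.params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 97]))
    t = session.t
    ch = session.channels
    paths = {}

    # overhead landmarks (subsample the 60 Hz truth to the overhead rate)
    step = max(int(round(p.rate / overhead_rate)), 1)
    idx = np.arange(0, t.size, step)
    tmpl = session.head_template
    head_coords = {}
    ang = np.deg2rad(ch["yaw"][idx])
    R = np.stack([np.stack([np.cos(ang), -np.sin(ang)], axis=-1),
                  np.stack([np.sin(ang), np.cos(ang)], axis=-1)], axis=-2)
    for j, nm in enumerate(tmpl.names):
        pt = (R @ tmpl.coords[j]) + np.stack([ch["x"][idx], ch["y"][idx]], axis=-1)
        head_coords[nm] = pt + rng.normal(0, overhead_noise_cm, pt.shape)
    ckxy = np.stack([ch["cricket_x"][idx], ch["cricket_y"][idx]], axis=-1)
    head_coords["cricket_body"] = ckxy + rng.normal(0, overhead_noise_cm, ckxy.shape)
    head_coords["cricket_head"] = (ckxy + np.array([0.5, 0.0])
                                   + rng.normal(0, overhead_noise_cm, ckxy.shape))
    paths["overhead"] = f"{out_dir}/overhead.csv"
    _write_tracker_csv(paths["overhead"], t[idx], overhead_rate,
                       list(head_coords), head_coords)

    # eye cameras at the session rate; pixel noise equivalent to sigma_meas
    px_noise = p.camera_scale * np.sin(np.deg2rad(p.sigma_meas))
    for eye, sign in (("right", 1.0), ("left", -1.0)):
        _, pts = project_pupil(sign * ch[f"theta_{eye[0]}"],
                               ch[f"theta_v_{eye[0]}"],
                               p.camera_center, p.camera_scale,
                               p.pupil_radius_px, pixel_noise=px_noise, rng=rng)
        coords = {f"pupil_{k}": pts[:, k, :] for k in range(pts.shape[1])}
        paths[f"eye_{eye}"] = f"{out_dir}/eye_{eye}.csv"
        _write_tracker_csv(paths[f"eye_{eye}"], t, p.rate, list(coords), coords)

    # IMU voltages at 50 Hz
    t_imu = np.arange(0.0, t[-1], 1.0 / imu_rate)
    pitch_i = np.interp(t_imu, t, ch["pitch"])
    roll_i = np.interp(t_imu, t, ch["roll"])
    yaw_rate = np.gradient(ch["yaw"]) * p.rate
    yaw_rate_i = np.interp(t_imu, t, yaw_rate)
    sp, sr = np.deg2rad(pitch_i), np.deg2rad(roll_i)
    ax = GRAVITY * np.sin(sp)
    ay = GRAVITY * np.sin(sr)
    az = GRAVITY * np.sqrt(np.clip(1 - np.sin(sp)**2 - np.sin(sr)**2, 0, 1))
    gz = np.deg2rad(yaw_rate_i)
    zeros = np.zeros_like(t_imu)
    paths["imu"] = f"{out_dir}/imu.csv"
    pd.DataFrame({
        "t": t_imu,
        "ax": ax / accel_gain, "ay": ay / accel_gain, "az": az / accel_gain,
        "gx": zeros, "gy": zeros, "gz": gz / gyro_gain,
    }).to_csv(paths["imu"], index=False)

    paths["ground_truth"] = f"{out_dir}/ground_truth.json"
    session.ground_truth.to_json(paths["ground_truth"])
    paths["meta"] = f"{out_dir}/session_meta.json"
    with open(paths["meta"], "w") as fh:
        json.dump({
            "params": asdict(session.params),
            "overhead_rate": overhead_rate,
            "imu_rate": imu_rate,
            "accel_gain": accel_gain,
            "gyro_gain": gyro_gain,
            "eye_sign": {"right": 1, "left": -1},
            "template": {nm: list(map(float, xy))
                         for nm, xy in zip(tmpl.names, tmpl.coords)},
        }, fh, indent=2)
    return paths
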