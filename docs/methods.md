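# Methods

## Conventions

Angles are degrees. Yaw is measured counter-clockwise (seen from above) from
the arena +x axis and wrapped to (−180°, 180°] at interfaces; all internal
gaze arithmetic runs on the unwrapped line so the seam never produces
spurious ±360° velocity spikes. Azimuth `A = yaw − bearing(head→cricket)` is
0 when the head points at the cricket and positive when the cricket is to
the right of the head axis (configurable sign). Both eyes are expressed in a
shared head frame with rightward-positive horizontal angle; the per-eye
image-to-head sign map (the two cameras view the head from opposite sides)
is a configuration item, default right eye +1 / left eye −1. Vergence
`V = θ_R − θ_L` is negative when converged. Positive pitch is nose-up.

## Timebase

Overhead video (30 Hz), eye cameras (60 Hz) and IMU (50 Hz) are acquired on
independent clocks. Every channel is linearly interpolated onto one uniform
60 Hz grid spanning the overlap of all streams. No extrapolation: samples
outside a stream's span, or bridging a dropped-frame gap longer than 1.5
nominal frame intervals, are NaN and stay masked through the analysis.
Angle channels are unwrapped before interpolation and re-wrapped after.
Median windows are converted to the nearest odd sample count ≥ 1 (500 ms at
60 Hz → 31 samples; 266.7 ms at 50 Hz → 13 samples) with the window
shrinking at series ends.

## Eye-camera calibration

Spherical-eye model: at angular offset θ from the camera axis the pupil
image has ellipticity `e = cos θ`, center displacement `|p − c| = R sin θ`,
and major axis perpendicular to `p − c`.

* **Ellipse fit.** Per frame, the 8 tracked pupil-edge points are fit by
  algebraic conic least squares. The default is the Taubin
  (gradient-normalized) form rather than the plain direct fit: both are
  closed-form and identical on clean data, but with 8 points and ~0.5 px
  noise the direct fit's ellipticity is biased low near e = 1 (measured
  ≈ −0.015), which feeds a large downward bias into the scale factor; the
  Taubin normalization cuts that bias about five-fold. The plain direct fit
  remains available (`method="direct"`). Frames with < 5 valid points,
  collinear points or hyperbolic solutions are flagged invalid.
* **Camera-axis center.** Frames with significant ellipticity
  (`e ≤ 1 − min_eccentricity`) each contribute one linear constraint
  `m·c = m·p` (m = unit major axis); the stacked system is solved by least
  squares, with a condition-number cap rejecting near-parallel constraint
  sets. Default `min_eccentricity = 0.01` (≈ ≥ 8° off-axis); for noisy
  tracker data the analysis scripts use 0.05 (≥ ~18°), because the
  ellipticity of near-circular frames is dominated by noise.
* **Scale factor.** From `|p − c| = R √(1 − e²)`. The default estimator is
  the through-origin least-squares slope of displacement on `√(1 − e²)`.
  Because tracking noise lives almost entirely in e (the displacement is
  comparatively clean), this regression direction is attenuation-biased
  under noise; `regression="inverse"` fits the reciprocal relation and
  inverts it, putting the noise on the response side, and is what the
  end-to-end scripts use. Both agree exactly on clean data.
* **Angles.** `θ_h = asin((p_x − c_x)/R)`, `θ_v = asin((p_y − c_y)/R)`;
  arguments outside ±1 are clipped with a warning and flagged. Central (0°)
  eye position is the mean pupil position over the recording's valid
  samples.
* **Eye measurement error** is estimated from stationary periods
  (speed < 1 cm/s, frame-to-frame head rotation < 1°) as
  `std(Δθ_h)/√2` — unbiased for iid noise; a pooled within-run position-std
  variant is exposed (`method="window_std"`) since the frame-difference
  convention is one of two reasonable readings.

## Head kinematics

The mean head geometry is a generalized-Procrustes template (rotation +
translation only, no scaling), iterated to 1e-6 RMS change; per-frame pose
is the closed-form weighted 2-D rigid fit (cross-covariance angle), with
landmark confidences as weights (0 below the 0.9 threshold). Yaw is the
fitted rotation plus the template's nose→head-center direction. Speed is
frame-to-frame displacement × rate, median filtered over 500 ms, and the
range rate is the central-difference derivative of cricket distance through
the same filter. The accelerometer is median filtered over 266.7 ms, then
`pitch = asin(a_forward/g)`, `roll = asin(a_lateral/g)` (clip + flag beyond
±g); the gyroscope is converted linearly without filtering. The IMU axis
map (which sensor axis is forward/lateral/yaw, with signs) is a
configuration item. Head measurement error is the RMS difference per frame
between landmark-fit Δyaw and the integrated gyro yaw rate.

## Epochs

Approach = speed > 1 cm/s AND |A| < 45° AND range rate < −10 cm/s, per
sample, strict comparisons (ties excluded). Runs become half-open
`[start, end)` intervals; post-processing merges gaps ≤ 100 ms and drops
intervals < 250 ms by default, and both can be set to 0 to recover exactly
the boolean conjunction. Moving = speed > 1 cm/s. Non-approach is the
complement of approach within the valid range.

## Gaze segmentation

`G = H + E` with `E = (θ_R + θ_L)/2`. Velocity is the central difference ×
rate (one-sided at the ends). |Ġ| strictly above 180 °/s → saccadic, else
compensatory; NaN stays invalid. Fixations are maximal compensatory runs ≥
50 ms. Saccadic runs separated by ≤ 1 non-invalid sample are merged (the
central difference smears a single-frame step over two samples and can dip
below threshold for one frame mid-shift); each run yields one saccade with
onset at the first suprathreshold sample, amplitude `G(end) − G(start−1)`,
and signed peak velocity. Because that single-sample amplitude carries the
full measurement noise, a plateau estimator
(`saccade_amplitudes_plateau`) that averages up to 12 compensatory samples
on each flank — where gaze is held constant by the VOR — is provided and
used when comparing against ground truth under noise. Stabilization is the
per-fixation RMS deviation about the within-fixation mean, reported for
gaze and head yaw with their medians.

## Summary statistics

Lagged cross-correlations are Pearson at each integer-sample lag (positive
lag = second series follows the first), with optional first differencing of
either series. Masked statistics are computed within mask-contiguous
segments only — differencing and correlation never cross an epoch boundary
— and combined per lag by sample-weighted averaging, so approach and
non-approach regimes don't mix. Note a structural fact about
saccade-and-fixate series: the frame-to-frame head-eye correlation computed
over *all* samples is bounded well away from −1, because the few large
saccadic reset steps carry roughly `n_comp/n_sacc` times the variance of
the compensatory steps; the compensation signature is therefore measured
within compensatory samples, where it is ≈ −1.

Saccade-triggered averages align (|azimuth|) traces on saccade onsets with
mean ± sem; partial windows are dropped by default. Pre/post-saccade
targeting samples |head azimuth| and |gaze azimuth| at onset − 100 ms and
onset + 50 ms: the pre offset sits inside the pre-saccadic head turn
(which lasts ~0.3 s), where the stabilized gaze lags the head — at −250 ms
the turn has typically not begun and the lag does not yet exist — and the
post offset samples just after the ~2-frame shift completes, before new
compensatory drift accumulates. Both are configurable. The pitch–vergence
relation is an ordinary least-squares line with Pearson r. Conditional
distributions (e.g. eye velocity while |head yaw velocity| < 15 °/s) use
configurable bins, default 5° for positions and 20 °/s for velocities.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes, plus
ground truth for every recovery test. Defaults define the study conditions:
45 × 38 cm arena, 600 s at 60 Hz, VOR gain 1.0, 15° saccade-trigger
eccentricity, 2-frame saccades, pitch–vergence slope −0.5, 0.5° measurement
noise.

* **Locomotion** alternates pause (mean 1.6 s) and move (mean 2.2 s) bouts;
  moving speed relaxes to 8 cm/s (OU, τ = 0.3 s). Reorientation happens as
  discrete head-turn bouts — raised-cosine yaw-velocity pulses, explore
  amplitude ~N(0, 16°) capped at 30°, peak velocity ≤ 350 °/s, separated by
  ≥ 0.25 s — because rodents turn in discrete bouts rather than continuous
  drift; a gentle wall-avoidance bout steers outward headings back toward
  the arena center.
* **Pursuit** starts from moving at 0.25 s⁻¹ when the cricket is > 8 cm
  away: one large orienting turn onto the cricket (cap 120°), then a
  full-speed chase (30 cm/s, braking inside 4 cm) with slower corrective
  bouts every 0.4 s. The cricket flees at 12 cm/s on a per-chase curved
  escape path once the mouse is within 10 cm, relocates on capture
  (< 2.5 cm) and occasionally at random; failed chases time out after 6 s.
  These dynamics exist so approach epochs are long enough to carry a usable
  number of saccades; ground-truth approach intervals are defined
  operationally as the three epoch criteria applied to the noiseless
  channels through the standard derivation pipeline.
* **Eyes.** The mean horizontal eye angle integrates −gain·Δyaw between
  saccades and linearly recenters to 0 over 2 frames when its eccentricity
  passes the 15° trigger, with a 3-frame refractory. The trigger is gated
  while a turn bout is in progress — saccades couple to head-turn
  completion, with mid-turn catch-ups at 2.5× the trigger that truncate the
  bout — and any saccade holds the next bout for 0.3 s. This yields the
  saccade-and-fixate pattern (a default session has ≈ 600 saccades, median
  fixation ≈ 0.55 s) while keeping eye eccentricity inside the |θ| < 90°
  projection domain. Vergence is slope·pitch plus OU noise (0.8°), split
  θ_R/L = θ_mean ± V/2; a small vertical eye process (OU, 5°) gives the 2-D
  pupil spread calibration needs.
* **Pitch/roll** are critically damped noise-driven oscillators
  (quasi-period 3 s; stationary std 10° exploring, 3° during approach —
  vertical head stabilization). The smooth (C¹) process is chosen so the
  266.7 ms accelerometer median filter tracks it closely; a raw OU path is
  rough at every scale and defeats short median filters.
* **Noise model.** The in-memory session channels are noiseless ground
  truth. Measurement noise is an overlay: `measured()` adds iid Gaussian
  0.5° to angle channels and 0.05 cm to positions; the raw-style file
  export adds the equivalent pixel noise (`R·sin(0.5°) ≈ 0.52 px`) to
  pupil-edge points and 0.03 cm to overhead landmarks. iid noise has no
  temporal structure, so detection results on the overlay say nothing about
  correlated tracker failures (occlusions, identity swaps) in real data.
* **Raw-style export** writes the overhead tracker CSV at 30 Hz (head
  points rendered from pose + template, cricket head/body), both eye CSVs
  at 60 Hz (8 projected edge points per frame), the IMU voltage CSV at
  50 Hz (gravity components from pitch/roll, gyro from Δyaw, with recorded
  gains), ground truth and a session-meta JSON — so the full pipeline runs
  end-to-end from files, exercising the multi-rate timebase.

## What the synthetic tests do and do not show

Passing recovery tests shows the pipeline's math is right under its own
model: exact spherical-eye projection, rigid planar head geometry, gain-1
VOR, iid noise. They do not certify performance on real recordings, where
VOR gain is below 1 and state-dependent, eye torsion and camera shake exist,
landmark errors are heavy-tailed and correlated, and the cricket is tracked
imperfectly. The generator's behavioral parameters (bout statistics, chase
gains, flee behavior) are design choices tuned once to produce sessions of
realistic scale, not estimates of mouse behavior.

## Numerical choices and degenerate inputs

Strict inequalities at every printed threshold (1 cm/s, 45°, −10 cm/s,
180 °/s); ties fall on the quiescent side. Ellipse fits require ≥ 5
non-collinear points; camera-center solving requires ≥ 2 frames and a
conditioned constraint set; asin arguments are clipped to ±1 with a flag;
empty masks, empty event lists and all-invalid series raise
`AnalysisError` rather than returning NaN silently. Epoch interval
arithmetic uses a 1 ns tolerance at merge/duration boundaries so time
shifts cannot flip sample-exact ties. All generator randomness derives from
one seed via independent child streams (behavior, eyes, noise overlay,
export), so sessions are bitwise reproducible and the noise overlay never
perturbs the behavioral trajectory.
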