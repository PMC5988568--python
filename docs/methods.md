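# Methods

`headmotion` reimplements, as a tested library, an analysis pipeline for 3D
head rotations of freely moving rodents measured with a head-mounted inertial
sensor, together with the spike-train analyses that relate collicular-style
bursting activity to those rotations. Because no animal recordings ship with
the package, every stage is validated by parameter recovery against the
synthetic-data module, which generates trajectories, IMU streams and spike
trains with the statistical structure the analyses assume.

## Coordinate conventions

The inertial (Earth) frame is x-north, y-east, z-down; the head frame is
x-nose, y-right-ear, z-down-through-the-head. The rotation matrix `R` maps
inertial vectors into the head frame (`v_H = R v_I`) and factors as
`R = Rx(phi) Ry(theta) Rz(psi)`: yaw `psi` about z is applied first, then
pitch `theta` about the carried y axis, then roll `phi` about the carried x
axis; positive angles are clockwise rotations. Gimbal lock occurs at
`theta = +/-90 deg`; the Euler extraction flags it rather than raising,
because a freely moving mouse essentially never points its nose straight up
or down. All public interfaces use degrees; internals use radians.

## Attitude estimation (DCM algorithm)

Gyroscope rates advance the matrix one 20-ms step at a time through the
first-order update `R^T(t+dt) = R^T(t)(I + Omega_x dt)` (stored as the
algebraically identical pre-multiplication of `R`). Numerical error is
controlled by a renormalization applied every step: the X/Y column
dot-product error is split half-and-half between the two columns, Z is
rebuilt as their cross product, and each column receives one Taylor step
`v <- (3 - v.v)/2 v` of magnitude adjustment. Two properties of this scheme
are worth recording:

* For unit columns with dot-product error `e`, the post-correction error is
  `e^3/4`, which satisfies the commonly quoted `e^2/4` bound; the bound is
  treated as an upper bound, not an equality.
* One Taylor magnitude step leaves an `O(eps^2)` norm residual (about 4e-3
  from a 5% error), and the scheme as a whole leaves an `O((omega dt)^2)`
  *orientation* residual per step for rotations about oblique axes, because
  rebuilding Z from X and Y is not the polar (closest-rotation) projection.
  At mouse head speeds this is microdegrees per step; it only matters when
  constructing exact round-trip tests (see the IMU generator below).

Gyro drift is corrected by a proportional-plus-integral feedback of two error
vectors: the magnetometer yaw error (cross product, in the inertial frame, of
the horizontal projection of the head x axis with the magnetometer-implied
heading, rotated into the head frame) and the accelerometer pitch/roll error
(cross product of the normalized accelerometer vector with the head-frame
image of the inertial z axis). The operand order of each cross product is
fixed by the requirement that the feedback *reduce* the attitude error under
the update convention above — the same sense used by the open-source AHRS
implementations this estimator family descends from; magnitudes equal the
sine of the misalignment either way. Default gains are
`KP_yaw = 1.2`, `KP_pitchroll = 0.02`, `KI_yaw = KI_pitchroll = 0.001`.
With these gains a constant yaw-rate bias of 1 deg/s settles below 1 deg of
steady-state yaw error, while pitch/roll biases are bounded and slowly
annealed by the integral term (the proportional tilt gain is deliberately
small so that linear accelerations do not corrupt the attitude).

The magnetic reference field is `(Bx, 0, Bz)` with default `(1, 0, 0)`; the
yaw extraction is algebraically insensitive to the inclination `Bz`, so only
the horizontal component matters. Accelerometer and magnetometer vectors are
normalized before use; near-zero vectors (free fall, dropouts) produce a zero
correction and a log entry rather than an error.

## Synthetic data

The generator's defaults are the package's canonical study conditions:

* **Sampling**: 50 Hz (`dt = 0.02 s`), five-minute trials, session structure
  light–dark–dark–light.
* **Movement events**: hold / smooth-displacement / hold, with exponential
  holds (about one event per second, ~300 per trial), movement durations
  uniform on 0.1–0.3 s, and a raised-cosine velocity profile (smooth,
  zero-endpoint-velocity; the field does not report a profile and this one
  avoids detector edge artifacts). Per-event extents are Gaussian per axis
  with SDs yaw 22.7, pitch 21.4, roll 18.3 deg. Roll extents carry a weak
  coupling of -0.102 deg/deg to the concurrent yaw extent, emulating the
  observed clockwise-yaw/counter-clockwise-roll conjunction; yaw x pitch and
  pitch x roll are independent.
* **Stationarity**: yaw diffuses freely (so azimuth is eventually sampled all
  around the circle), while pitch and roll mean-revert toward level with
  reversion 0.5 per event. The injected noise is rescaled so the stationary
  per-event *extent* SD still equals the requested sigma exactly; the
  stationary *position* SD then also equals that sigma, which keeps pitch far
  from gimbal lock and concentrates elevation/bank sampling in the +/-45 deg
  analysis range, as for a real head.
* **Constrained kinds**: `listing` confines quaternions to the zero-torsion
  plane by construction; `fick` nests pitch inside a space-vertical yaw axis
  (identically the package's Euler order with zero roll); `helmholtz` nests
  yaw inside a space-horizontal pitch axis. `rotation_table` reproduces the
  constant-velocity bench validation.
* **IMU emulation**: the accelerometer reads `R (0,0,1)` (gravity direction)
  and the magnetometer `R (Bx,0,Bz)`; white-noise SDs default to 0.5 deg/s
  (gyro) and 1% of magnitude (accelerometer/magnetometer), with an optional
  constant gyro bias. The per-step gyro rate is defined as the rate whose
  *discrete estimator step* (first-order update followed by renormalization)
  carries `R(t)` exactly onto `R(t+dt)`, found by a short fixed-point
  iteration seeded with the tangent-scaled axis-angle of the relative
  rotation. This makes the noiseless zero-bias stream exactly invertible by
  the estimator, which is the property the round-trip validation relies on;
  it differs from the instantaneous physical rate by `O((omega dt)^2)`,
  far below the sensor noise floor.
* **Neurons**: `displacement_tuned` cells emit one burst (3+ spikes at
  ~70 Hz, ISIs jittered +/-30%) starting 80 ms before the onset of each
  selected movement event, with reliability 0.8 and a Poisson baseline
  (default 1 Hz). Events are selected per constrained axis through an extent
  window of half-width `(2/3) |preferred|` whose *center is shifted* so the
  truncated-Gaussian mean of accepted extents equals the preferred component
  exactly — a window centred on the preferred value would plant a cell whose
  measured mean displacement is shrunk toward zero, because small extents are
  more common. `ahv_tuned` cells are inhomogeneous Poisson with a
  skewed-Gaussian rate–velocity curve, default `(A, mu, sigma, gamma) =
  (7000, 150, 100, 2)`; this planted curve is deliberately narrow and skewed
  because broad symmetric curves are not identifiable under five-minute
  velocity sampling (the center/skewness trade-off of the model family leaves
  near-equivalent fits tens of deg/s apart). `azimuth_tuned` cells have a
  von-Mises-shaped rate over yaw heading; `untuned_poisson` cells are
  homogeneous. All generators are deterministic under a fixed seed.

What the generator does *not* emulate: neck biomechanics, translation and its
accelerometer contamination, magnetic-field distortions, spike-sorting noise,
non-Poisson baseline statistics, light/dark behavioral differences, and any
real correlation structure between cells. Passing recovery tests therefore
demonstrates the correctness of the analysis chain under its own model
assumptions, not performance on animal data.

## Kinematics

A motion event in one Eulerian component is a maximal run of same-sign
per-bin velocity containing a core of at least 100 ms (five bins at 50 Hz)
strictly faster than 25 deg/s (0.5 deg/bin), extended backward and forward to
the last same-direction bin; zero velocity terminates the extension, and
events whose summed extent is 2.5 deg or under are discarded as jitter.
Threshold readings: "over 0.5 deg per bin" is a strict inequality for the
core, while extension needs only direction agreement. Displacement
distributions use 36 ten-degree bins normalized to their maximum with a
least-squares Gaussian fit. Conjunctive pairs sum the second component's
velocity over the first component's event window (the only window the event
definition provides); events beginning simultaneously in both components are
counted once, per pair.

## Donders geometry

Orientations are unit quaternions `(q0, qT, qV, qH)` (scalar first; torsional
= x, vertical = y, horizontal = z components), hemisphere-normalized to
`q0 >= 0`. Quaternion algebra is the Hamilton convention; the inverse of a
unit quaternion is its conjugate. Re-referencing to the primary position
fits the displacement plane `qT = a1 + a2 qV + a3 qH`, right-multiplies by
the inverse of `h = (sqrt(1-a1^2), a1, 0, 0)` when `a1 != 0`, refits, and
left-multiplies by the inverse of the primary quaternion built from the
refit plane's unit normal. Exactly one re-referencing pass is performed and
the angular difference between the two planes is reported.

Surface fits are ordinary least squares minimizing torsional residuals: a
plane (first order), the full quadratic (second order; the `qV qH`
coefficient is the twist score), or the one-parameter gimbal form
`qT = s qV qH / q0` whose coefficient `s` is -1 for a Fick gimbal, +1 for
Helmholtz, 0 for a Listing plane. When more than 1000 samples are available
a seeded uniform subsample of 1000 is fit. The torsional SD (Tsd) converts
each residual to a torsion angle by the exact `2 asin(r)` before taking the
SD; for the small residuals of near-Donders data this equals the small-angle
`2r` conversion to first order.

## Burst-displacement tuning

Bursts are maximal runs of 3+ spikes with inter-spike intervals of at most
50 ms spanning at least 20 ms (with a 1-ns tolerance against float rounding);
cells need five bursts per trial to be testable, and the within-burst rate is
the ISI-based `(n_spikes - 1)/duration`. The burst-triggered average zeroes
heading at each onset, spans 500 ms before to 1 s after it, and scores each
burst by the signed max-minus-min of the following 500 ms (positive when the
minimum comes first; ties take the earliest extremum, so flat segments score
exactly zero; bursts whose window leaves the trial are dropped). The null
rigidly shifts burst onsets by a uniform 20–150 s (capped at the trial
length, with a log entry, for short trials) modulo the trial length, 1000
times; a component is tuned when the mean displacement escapes the same side
of the 2.5/97.5-percentile band in both light trials with a consistent sign.
Under the default conditions this joint rule holds the per-cell false-positive
rate well under 2%.

Timing of bursting relative to motion is summarized as z-scored burst-onset
counts in 20-ms bins over +/-500 ms around motion onsets (histogram edges are
built with `linspace` so that 0 is an exact edge), with mean z reported for
the four 80-ms windows starting at -160, -80, 0 and +80 ms. All window
lengths throughout the package are stored in seconds and converted to bin
counts at the sampling interval in use, so a non-default `dt` preserves the
500-ms / 1-s / 100-ms semantics.

## AHV tuning

Angular head velocity is the per-bin first difference scaled to deg/s and
smoothed with a centered 100-ms boxcar. Rates are computed per 20-deg/s bin
over +/-500 deg/s, dwell-normalized, and normalized by the maximum bin.
Bins visited for less than 0.2 s are excluded (their rate estimates are
dominated by sampling noise and, being unweighted in the least squares, can
otherwise dominate the fit); excluded bins also drop out of `n` in the BIC.
The constant model (one parameter, the intercept) and the skewed Gaussian
`A/(sigma sqrt(2 pi)) exp(-(x-mu)^2/(2 sigma^2)) (1 + erf(gamma (x-mu)/(sigma
sqrt(2))))` (four parameters) are fit by least squares with lmfit, from the
reference starting point (center 0 bounded +/-500, sigma 200 bounded
100–500, gamma 0 bounded +/-5) extended to a deterministic multi-start over
amplitude, center and gamma initials, keeping the best final sum of squares:
a zero starting amplitude alone leaves the optimizer on the constant-model
null, and the center/gamma trade-off has local minima. `BIC = ln(n) k -
2 ln(Lhat)` uses the Gaussian-residual likelihood with variance `RSS/n`.
A cell is AHV-modulated when the skewed model undercuts the constant model by
10+ BIC points and the fitted center's sign matches the cell's displacement
direction.

## Allocentric heading

Tuning curves divide spike counts by dwell time per heading bin: 36 ten-degree
bins for azimuth, twenty five-degree bins over +/-45 deg for elevation and
bank (out-of-range samples and their spikes are excluded). The Rayleigh
vector is the mean resultant length of the rate-weighted bin-center
distribution, `r = sqrt(x^2 + y^2)` with `x = sum(rate cos)/sum(rate)` and
likewise for `y` — the standard head-direction computation, which maps a
single-bin curve to exactly 1 and a flat curve to 0. Azimuth modulation
requires `r` above the 95th percentile of the spike-time-shuffled null in
both trials and preferred directions (bin centers of maximum rate) within
30 deg. Elevation/bank use the tuning width: the percentage of bins whose
rate exceeds `min + 0.25 (max - min)` — a threshold above the minimum is the
reading that discounts background firing — with modulation requiring a width
below the null's 5th percentile in both trials; flat curves (max = min) have
width 100% and are never modulated. The anticipatory scan recomputes `r` at
spike-time shifts of -100 to +100 ms in 20-ms steps. The widely used 0.4
Rayleigh benchmark for head-direction cells is reported by examples but never
used for classification.

## Pipeline

`run_pipeline` chains simulation, attitude estimation, kinematics, Donders
fits, burst-tuning classification (across the two light trials), AHV model
selection and allocentric tests, serializing every stage's inputs and outputs
as CSV/JSON under the output directory; a fixed seed makes the whole report
reproducible bit for bit. The light/dark structure is label-based grouping
only — no sensory modeling is attempted.

## Problem sizes used by the validation suite

The test suite and the acceptance script run entirely on synthetic data at
the canonical conditions: five-minute 50-Hz trials, 1000-rep shuffled nulls,
1000-point surface fits, and 200 independent sessions for the
false-positive-rate calibration of the two-trial classifier. Donders-surface
and Rayleigh benchmarks use constructed orientation clouds and tuning curves
of 1000 points and 36 bins respectively.

## Known limitations

* The estimator inherits the reference renormalization scheme; at per-step
  rotations far above mouse head speeds its single-pass orthogonalization
  leaves orientation residuals of order `(omega dt)^2` per step.
* The skewed-Gaussian rate model has no baseline term, so cells with a
  substantial velocity-independent rate bias the fitted center; the planted
  AHV cells are therefore generated with velocity-driven rate only.
* Tsd uses the SD of torsion angles about their mean; for the
  intercept-free gimbal-form fit a nonzero mean residual is possible, in
  which case Tsd measures scatter about that mean rather than RMS distance
  to the surface.
* The two-trial classifier's false-positive rate depends on the null's
  percentile estimates; with far fewer than 1000 shuffle repetitions the
  band estimates become noisy and marginal exceedances more common.
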