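# Methods

## Frames, signs, and the orientation representation

All computation uses the aerospace north-east-down (NED) frame: X north,
Y east, Z toward the Earth's centre. Gravity is `+g` along Down
(g = 9.80665 m/s², configurable), so a stationary accelerometer reads the
specific force `(0, 0, −g)`. Orientation is carried exclusively by unit
quaternions `(q0, q1, q2, q3)`, scalar first, Hamilton convention; Euler
angles exist only for the stabilization display and are never used in the
kinematics, precisely to avoid gimbal lock.

One convention decision ripples through everything: the quaternion stored in
an orientation track is the **earth→body** rotation, i.e. the quaternion
whose rotation matrix must be *inverted* (transposed) to bring device
accelerations into the earth frame. `rotate_body_to_earth(q, v) = R(q)ᵀ v`
is the only earth-mapping operation the quaternion module exposes, so the
sign convention cannot be half-applied downstream. The fusion filter's
internal state is the conjugate (the body→earth attitude), which is the
convention the published filter equations use (`q̇ = ½ q ⊗ (0, ω)`).
Quaternions are re-normalized after every product: a capture chains
thousands of multiplications and the norm would otherwise drift.

## The orientation filter

Each step propagates the attitude by gyro integration and corrects it along
the negative normalized gradient of a measurement objective:

    q ← normalize( q + (½ q ⊗ (0, ω) − β ∇F/‖∇F‖) · Δt )

`F` stacks two residuals: predicted vs measured gravity direction (earth
reference `(0, 0, −1)`, the unit specific force at rest) and predicted vs
measured magnetic field direction. The magnetic earth reference is
re-derived from the measurement each step as `(b_x, 0, b_z)` — the
horizontal-plus-vertical NED decomposition — so a wrong assumed declination
cannot tilt the estimate; the configured `magnetic_reference` (default 60°
inclination, 0.45 gauss in the generator) only defines the simulated world.

**Gain.** β is the correction authority in rad/s. The default is 0.041, the
value recommended in the filter's original publication for 9-DoF operation.
This matters here: a swinging arm holds ~1 g of centripetal acceleration for
seconds at a time, and the accelerometer residual then points somewhere
other than gravity. At β = 0.1 that sustained disturbance tilts the attitude
enough to inflate a reconstructed 1.0 m arc radius to ~1.5 m; at 0.041 the
tilt stays small enough for trajectory work while a stationary warm-up still
converges from a 30° initial error to < 0.01° well inside the 20 s
stabilization window. β = 0 reduces the filter to exact gyro integration,
which the tests exploit as a closed-form check.

**Warm-up.** The filter starts at identity; a 20 s stabilization phase
absorbs the initialization error before a capture is trusted. Convergence is
declared when yaw, pitch and roll each vary by less than 0.5° over the last
second. A constant gyro bias does not destroy this — it shifts the fixed
point by a bounded tilt (< 2° at 0.5 deg/s bias), which the long-run
fixed-point test pins down.

**Degenerate input.** A zero accelerometer vector has no direction; that
step falls back to pure gyro propagation and logs a warning rather than
dividing by zero.

## The processing chain

Order: fuse → rotate to earth → subtract gravity → smooth → integrate to
velocity → high-pass → ZUPT → speed → integrate to position. Stages and
their defaults:

- **Smoothing**: trailing moving mean over N = 50 samples (100 ms at
  500 Hz), recomputed each sample; startup uses the mean of the samples seen
  so far. The device firmware calls this an EWMA, but the computation it
  performs — sum N, divide by N — is an equal-weight boxcar mean, so that is
  the default; a true exponential mean (α = 2/(N+1)) sits behind
  `smoothing_mode="exponential"` for strict readers of the name. The
  measured −3 dB point of the 50-tap boxcar at 500 Hz is 4.43 Hz. (A
  "≈115 Hz cutoff" is sometimes quoted for this filter; no standard
  moving-average formula yields it, so the measured value is what this
  package documents.)
- **Integration**: left-rectangle rule (cumulative sum × Δt), zero initial
  velocity, origin (0, 0, 0). Position is integrated from the
  ZUPT-corrected velocity and is deliberately *not* filtered afterwards —
  filtering position would erase genuine displacement.
- **Drift removal**: first-order single-pole high-pass on each velocity
  component, `y[n] = α(y[n−1] + x[n] − x[n−1])`, α = RC/(RC + Δt). The
  device's printed setting is a 50 Hz cutoff and remains the
  `PipelineConfig` default, but note the physics: at 500 Hz sampling a
  first-order 50 Hz high-pass passes only ~2% of a 1 Hz component and ~10%
  of a 5 Hz component — essentially the entire band of human limb motion is
  removed. For actual trajectory reconstruction
  `PipelineConfig.reconstruction()` keeps every other default and sets a
  0.1 Hz cutoff (|H| ≥ 0.994 at 1 Hz), which removes integration drift and
  DC while leaving the motion band intact; this is what the CLI and the
  end-to-end tests use. The tension between the printed value and usable
  output is documented here rather than silently "fixed": both settings are
  one flag apart.
- **ZUPT**: a sample is quiet when all three smoothed dynamic-acceleration
  components lie strictly inside ±0.3 m/s²; every maximal run of ≥ 60
  consecutive quiet samples (120 ms) has its velocity set to exactly 0.0.
  The test applies to the smoothed signal because that is the signal the
  chain has at that stage. This is the device's defence against residual
  integration error: a throw's natural pauses re-anchor the velocity.
- **Speed**: per-sample Euclidean norm of the corrected velocity —
  identically zero across ZUPT windows by construction.

The chain is deterministic: identical capture and configuration give
bit-identical tracks.

## The synthetic generator

`TrajectorySpec` carries a position path and a body→earth attitude path on
`[0, T]`; `simulate_truth` samples them at the capture rate and
differentiates by central differences (presets also provide analytic
derivatives, which the tight tests use — central differences are exact on
linear paths and within 0.1% on the circular ones). `truth_to_imu` is the
exact forward model the pipeline inverts: body specific force
`R(q)ᵀ(a_earth − g_vec)`, body rates `2 vec(q* ⊗ q̇)`, magnetometer
`R(q)ᵀ B_earth` sampled-and-held at its 40 Hz output data rate on the
0.002 s capture clock (a polling loop reads the last completed conversion;
the hold repeats the same noise draw, as a real register read would).

Noise defaults, chosen as plausible for this sensor class and all
configurable: accelerometer σ = 0.05 m/s²; gyro σ = 0.2 deg/s, constant
bias 0.5 deg/s per axis, slow ramp 0.01 deg/s per second; magnetometer
σ = 0.005 gauss. A single integer seed drives every draw; equal seeds give
bit-identical captures.

**Discus preset.** Six seconds, 3000 samples: hold (0–0.8 s), reverse
half-arc wind-up (0.8–2.0 s, `windup_fraction` = 0.5 of a full circle),
forward turn (2.3–3.7 s, one full revolution), release arc (3.9–4.9 s,
peaking at `release_speed`, default 15 m/s on a 0.9 m arm-plus-shoulder
radius, ≈ 955 deg/s of yaw), then rest. Angular velocity is built from
smooth sin² bumps, so the speed profile has exactly three local maxima with
the global maximum at release — two maxima when the wind-up is disabled —
and near-zero-speed gaps between phases long enough (≥ 60 quiet samples)
for the ZUPT to anchor. Release speeds requiring more than the ±2000 dps
gyro full scale are rejected as infeasible. The wrist yaw tracks the arc
tangent; the hand lifts 0.4 m during release so the side view shows the
throw elevation.

**What the generator does not model** — and therefore what passing tests do
not show about real data: accelerometer full-scale saturation (a genuine
15 m/s release on a 0.9 m radius exceeds ±8 g; the real device would clip),
soft/hard-iron magnetic distortion beyond linear calibration, device
flex/strap vibration, temperature-dependent bias, and any biomechanical
validity of the arm path. The end-to-end recoveries (peak speed within 10%,
arc radius within 20%) quantify the *processing chain's* fidelity under
clean conditions, with the dominant loss being the 100 ms smoothing window
acting on an acceleration vector that rotates at up to ~17 rad/s during
release — not a statement about field accuracy.

## Calibration and codec details

Calibration applies given per-axis constants, `(raw − offset) · slope`;
estimating them from maneuvers is out of scope (a convenience helper infers
accelerometer offsets from a level stationary segment, clearly marked as a
package convenience). Raw counts convert at `2·FS/2¹⁶` per LSB — 0.244 mg
for the ±8 g accelerometer; the 70 mdps and 0.29 mgauss figures quoted for
the other sensors are datasheet sensitivities that do not equal `2·FS/2¹⁶`
and are stored as data only.

The telemetry frame is four 5-byte ASCII `xx.xx` fields (x, y, z, speed), 20
bytes per sample, 60 000 bytes for a default capture. Values are quantized
to 2 decimals by round-half-away-from-zero (with −0.0 normalized to +0.0)
before encoding, making encode/decode exactly inverse on the 0.01 grid. The
field format carries no sign, so the default "offset" mode shifts each
coordinate axis by a per-capture constant — the floor of the axis minimum on
the 0.01 grid, guaranteeing non-negative fields — and reports the offsets in
a header record (a JSON sidecar for file streams); "strict" mode instead
rejects negatives. Overflow past 99.99 is always an error, never silent
saturation.

## Problem sizes in the test suite

The suite runs everything at the native capture regime (500 Hz, 3000-sample
captures) where the property concerns a capture; warm-up and convergence
tests run the full 20 s (10⁴ filter steps). The independent cross-check of
the fusion filter — a reference implementation whose correction direction is
a finite-difference gradient of the measurement objective, with rotations
through scipy — runs on the first 3 s of three noise-free preset streams,
enough for the two routes to diverge if either Jacobian or convention were
wrong. Randomized contracts use 10⁴ codec round-trips and 10⁴ ZUPT cases
against a naive window-sweep oracle. The noise-monotonicity check uses 20
seeded replicates per noise level on a 3 s out-and-back motion.
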