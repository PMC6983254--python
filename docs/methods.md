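# Methods

## Signal model and assumptions

A triaxial accelerometer measures specific force: at rest, the gravity
vector expressed in the sensor frame, with magnitude 1 g; under movement,
gravity plus body acceleration. All internal signals are in units of g
(1 g = 9.80665 m/s²). The calibration recovers the rotation **R** from the
sensor frame to a world frame with z up and x forward, under three
assumptions about the recording:

1. when at rest, the wearer is in the neutral (upright) posture most of the
   time, so the average quasi-static reading points along body-down;
2. sustained non-gravitational acceleration is absent (no free fall, no
   centrifugation), so the low-frequency reading is gravity;
3. movement variance concentrates in the vertical plane through the forward
   axis (locomotion), so the dominant horizontal motion direction is
   forward.

Violations degrade the estimate gracefully: lying episodes and shifted-mount
intervals that pass the quasi-static test bias the gravity average in
proportion to their share of the rest time, and near-isotropic horizontal
motion makes the heading unreliable (reported via the planarity ratio, see
below) without affecting the gravity alignment.

## Pipeline

**Filtering.** All stages share one filter family: a Butterworth filter,
order 4 per pass, applied forward and backward (zero phase; the magnitude
response is applied twice), with the cutoff quoted as the single-pass −3 dB
point. The paper-facing cutoff separating gravity from motion is 0.1 Hz.
The filter is realized as second-order sections; at normalized cutoffs as
low as 0.1 Hz / 30 Hz Nyquist a transfer-function realization loses
precision. Edges are handled by odd-reflection padding of 3×order samples,
so records need only be longer than 12 samples to filter, and the smoothing
window is a centered Hann taper of round(window·fs) samples (forced odd,
weights normalized; truncated and renormalized at the record edges).

**Quasi-static detection.** Motion intensity = Hann-smoothed (2 s) absolute
value of the high-passed (0.1 Hz) acceleration magnitude. Rectification
before smoothing makes positive and negative excursions both count as
motion. Samples with intensity < 0.02 g, in runs of ≥ 2 s, are
quasi-static. The 0.02 g threshold sits about 3 smoothed-noise standard
deviations above the expected intensity of pure sensor noise at σ = 0.02 g
per axis (mean ≈ σ·√(2/π) ≈ 0.016 g), so typical noise passes and any
magnitude-modulating movement fails. Note that motion exactly orthogonal to
gravity perturbs the magnitude only to second order and can evade a
magnitude-based detector; real locomotion always has a vertical component,
which is first-order.

**Gravity estimate.** The three axis channels are low-passed at 0.1 Hz and
averaged over the quasi-static samples; the mean is normalized to **ĝ**.
The mean magnitude over those samples is reported for quality control (it
should be ≈ 1 g). An empty mask raises a no-quasi-static error; a mean
shorter than 0.1 g is degenerate and also raises.

**Gravity alignment.** **R′** is the minimal rotation taking **ĝ** to
(0, 0, −1), built by the Rodrigues formula about the axis **ĝ** × (0,0,−1).
For the antipodal input (0,0,+1) the axis is undefined; the tie-break is a
π rotation about +x, also used within 1° of the antipode for stability.

**Heading.** The levelled samples minus the constant (0, 0, −1) g are the
motion residual; constant subtraction (rather than a second high-pass) is
used because after levelling the gravity term is a known constant. The
non-quasi-static rows' (x, y) columns form an m′×2 matrix; its SVD gives
σ₁ ≥ σ₂ and the leading right-singular vector **v₁** (equivalently the
leading eigenvector of the 2×2 covariance, which the tests use as an
independent oracle). Quasi-static rows are excluded — they contribute only
noise variance and would dilute the motion signal. The sign of **v₁** is
fixed so v₁ₓ ≥ 0 (ties: v₁ᵧ ≥ 0); the forward/backward ambiguity is
inherent and corrected manually via `flip_heading`. The composed rotation
is **R** = R_z(−θ)·**R′** with θ = atan2(v₁ᵧ, v₁ₓ). A planarity ratio
σ₁/σ₂ < 1.2 attaches an isotropic-motion warning rather than failing:
the gravity alignment is still valid, only the heading is suspect.

**Flagging.** On a calibrated record, the deviation signal is the angle
between the low-passed reading and vertical; samples whose low-passed norm
falls below 0.1 g are NaN (direction meaningless) and count as
above-threshold. Runs above the user threshold (default 15°) separated by
less than the minimum duration (default 10 s) are merged — one physical
event should not fragment — and runs shorter than the minimum are dropped.
Defaults are chosen to ignore brief bends but catch naps and mount shifts.
Flags are advisory: shifted sensor and genuinely non-upright posture look
identical to the deviation signal, and the distinction is left to the user.

**Activity.** Intensity = Hann-smoothed |‖a‖ − lowpass(‖a‖)| — the
motion-band magnitude. A plain smoothed magnitude would track gravity
(≈ 1 g) in every state; subtracting the low-passed baseline makes idle ≈ 0
and is the minimal construction that separates three states by
thresholding. Defaults 0.05 g (walk) and 0.4 g (run) fall between the
plateau intensities of the generator's surrogate gaits (idle ≈ 0.016 g,
walk ≈ 0.13 g, run ≈ 0.45 g) and are plausible for waist or thigh mounts.
Bouts shorter than 2 s are absorbed, shortest first, into the longer
adjacent bout (ties prefer the earlier), which removes the sub-2-s label
chatter that thresholding produces while the smoothed intensity ramps
through the walk band at idle↔run transitions.

**Tilt and summaries.** The tilt angle is the same computation as the
flagging deviation signal, exposed as a kinematic output. Window summaries
report the percentage of samples labelled walk and run and the NaN-ignoring
mean tilt per non-overlapping window (default 1 h); the mean (not median)
matches the single per-window angle such tables usually report. A trailing
partial window is kept when it covers ≥ 10% of the window length.

## Synthetic recordings

The generator builds world-frame specific force per scripted event —
still: (0, 0, −1) g; walk: sinusoids at 1.8 Hz, 0.15 g on x and 0.20 g on z
(90° out of phase); run: 2.8 Hz, 0.5 g and 0.7 g; lie: gravity re-expressed
for a body tilted 90° about the world y axis, no locomotion — maps each row
through the mounting rotation in force at that time, and adds i.i.d.
Gaussian noise (default σ = 0.02 g per axis). Shift events instantaneously
replace the mounting rotation. Everything is determined by the scenario
seed.

The waveforms are surrogates, not biomechanics: fixed-frequency sinusoids
with amplitudes chosen to separate the three intensity classes and to give
the heading SVD a dominant axis. Real gait has harmonic-rich, variable
waveforms, soft-tissue artifacts, posture drift and non-neutral rest;
passing tests on these scenarios demonstrates the estimator logic
(geometry, filtering, thresholds, bookkeeping), not field-grade accuracy.

Presets: `walk-calibration` (10 min, 60% rest, two walking bouts) is the
unit of the rotation-recovery batch; `activity-script` is a 5-min
idle–walk–run–walk–idle sequence; `lab-routine` is a 15-min mix of 6 walks,
2 runs and 2 lying episodes with three deliberate sensor shifts, each
tilting the mounting 30° for 35 s before restoring it, so that every
perturbation yields one bounded flagged interval (5 expected flags in
total); `upright-control` is the same routine without shifts or lying.

## Numerical choices and edge cases

- Sampling rates inferred from timestamps are rounded to 1 µs resolution so
  write→read round-trips preserve fs exactly; a gap deviating more than
  half a nominal period raises a sampling error naming the first bad index.
- Unit auto-detection treats a median magnitude in [6, 16] as m/s²
  (resting readings are ≈ 1 g or ≈ 9.81 m/s², well separated) and is
  idempotent.
- Quasi-static detection requires records longer than 2/cutoff (20 s at
  defaults) so the high-pass can separate motion from gravity.
- All emitted rotations are orthonormal with det +1 to ~1e-15; applying a
  matrix that fails this check at 1e-6 raises an invalid-rotation error.
- The heading SVD needs ≥ 3 motion rows; σ₂ = 0 yields an infinite
  planarity ratio rather than a division error.
- `flip_heading` is an involution to machine precision; headings are
  wrapped to (−π, π].
- Long records can be calibrated per segment (CLI `--segment start:end`,
  repeatable), mirroring per-day recalibration of multi-week recordings.

## Problem sizes

The recovery batch uses 50 recordings of 10 min at 60 Hz (36 000 samples
each); the flagging and activity scenarios are single 15- and 5-minute
recordings; the oracle-equivalence check uses 100 instances of ≤ 500 rows.
At these sizes the full pipeline runs in seconds on one core while leaving
the statistical margins (noise averaging over ≥ 10⁴ samples) wide.

## Known limitations

- Forward vs backward is unresolved by construction; the flip is manual.
- Heading quality degrades when horizontal motion is isotropic (planarity
  ratio near 1) — reported, not repaired.
- A magnitude-based motion test cannot see motion exactly orthogonal to
  gravity (second-order effect only).
- Rest spent substantially non-upright (long naps within a calibration
  window) biases **ĝ** toward the lying direction; calibrate per segment
  between flagged intervals in such cases.
- No gyroscope or magnetometer fusion, no time-varying orientation within a
  segment, and no resampling of irregular streams.
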