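# postucal

Orientation calibration and preprocessing for body-worn triaxial
accelerometers used in posture tracking.

Long field recordings (days to weeks at ~60 Hz) from accelerometers worn on
the trunk, pelvis or thigh are only interpretable as posture if the
orientation of the sensor on the body is known — and in the field the sensor
is mounted in an arbitrary, unknown orientation that can also shift when the
wearer removes and reattaches it. `postucal` recovers the full 3-DOF
rotation **R** that maps the sensor frame into the gravity-aligned world
frame, automatically and from the data alone, and provides the surrounding
pipeline: quasi-static detection, miscalibration flagging, idle/walk/run
labelling, tilt angles, per-window summaries, a CLI, and a synthetic-signal
generator with ground truth for validation.

## Method

An accelerometer at rest measures the gravity vector in its own frame; under
locomotion, most movement variance lies along the wearer's forward axis.
These two facts fix the three rotational degrees of freedom:

1. **Quasi-static detection.** The motion intensity is the 2-s
   Hann-smoothed, rectified, high-passed (zero-phase Butterworth,
   cutoff 0.1 Hz) acceleration magnitude ‖a‖. Samples below a threshold
   (default 0.02 g) in runs of at least 2 s are quasi-static.
2. **Gravity alignment (2 DOF).** The low-passed axis channels are averaged
   over quasi-static samples and normalized to the unit vector **ĝ**. The
   minimal rotation **R′** (about the axis **ĝ** × (0,0,−1)) maps **ĝ** onto
   the downward vertical: **R′ ĝ** = (0, 0, −1).
3. **Heading from SVD (1 DOF).** After levelling by **R′** and subtracting
   gravity, the horizontal (x, y) components of the motion samples form a
   matrix whose leading right-singular vector **v₁** is the dominant
   horizontal motion direction — taken as forward. With
   θ = atan2(v₁ᵧ, v₁ₓ), the full calibration is **R** = R_z(−θ) · **R′**.

Variance cannot distinguish forward from backward; the sign of **v₁** is
fixed deterministically and a manual π flip (`flip_heading`, CLI `--flip`)
is provided. A planarity ratio σ₁/σ₂ near 1 marks the heading as unreliable.

On top of the calibration: segments whose low-passed gravity direction
deviates from vertical beyond a threshold (default 15°) are flagged as
sensor shifts or sustained posture changes; a rotation-invariant intensity
signal thresholded at 0.05 g / 0.4 g labels idle, walking and running; and
the tilt angle to vertical is summarized per window together with the
walking/running percentages.

## Worked example

```python
import numpy as np
from postucal import (rotation_from_tilt_heading, walk_calibration_scenario,
                      generate_recording, auto_calibrate, apply_calibration,
                      label_activity, tilt_angle, summarize_windows)

# 10-minute synthetic recording: sensor mounted 40° off vertical at 25°
# heading, two walking bouts, noise σ = 0.02 g
mounting = rotation_from_tilt_heading(tilt_deg=40.0, heading_deg=25.0)
series, truth = generate_recording(
    walk_calibration_scenario(true_rotation=mounting, seed=42))

result = auto_calibrate(series)
print(f"estimated heading : {np.degrees(result.heading_rad):.2f} deg")
print(f"quasi-static used : {result.g_hat.n_samples} samples")
print(f"planarity ratio   : {result.planarity_ratio:.1f}")

calibrated = apply_calibration(series, result.R)
labels = label_activity(calibrated)
tilt = tilt_angle(calibrated)
for s in summarize_windows(calibrated, labels, tilt, window_s=600.0):
    print(f"window {s.start_s:.0f}-{s.end_s:.0f} s: walk {s.walk_pct:.1f}%, "
          f"run {s.run_pct:.1f}%, mean tilt {s.mean_tilt_deg:.2f} deg")
```

prints

```
estimated heading : 25.02 deg
quasi-static used : 21299 samples
planarity ratio   : 5.3
window 0-600 s: walk 40.1%, run 0.0%, mean tilt 0.09 deg
```

The estimated heading matches the scenario's 25° mounting to 0.02°; the
recovered rotation differs from the true mounting inverse by 0.021°
(geodesic angle). The calibrated record is upright (mean tilt ≈ 0°) and 40%
of its samples are labelled walking, matching the script.

The same pipeline is available as estimators that compose with
scikit-learn (`AccelCalibrator`, `QuasiStaticDetector`,
`ActivityClassifier`, `OrientationErrorFlagger`) and from the shell:

```bash
postucal simulate --preset lab-routine --seed 7 --output sim.csv --truth truth.json
postucal calibrate --input sim.csv --output calibrated.csv --report calib.json
postucal flag --input calibrated.csv --threshold-deg 15 --report flags.json
```

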