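# sidewinderkin

Tools for analysing sidewinding locomotion from digitized 3-D marker
trajectories: waveform kinematics extraction, allometric scaling statistics
and observed-variable path analysis, plus a synthetic-data generator that
makes every stage testable against known ground truth.

Sidewinding is the limbless gait in which sections of the snake's body hold
static ground contact while other sections are lifted up and forward; the
direction of travel is oblique to the body axis. From per-frame x,y,z
positions of 10 painted body markers, this package computes, per trial:

* whole-animal (marker-centroid) mean and peak speed and acceleration,
* per-marker peak speed (mid-body markers 3–7) and height lifted (markers
  2–8),
* the body wave's cycle frequency *f*, wavelength λ, peak-to-peak
  amplitude *A* and signed skew angle σ (positive = head-wards tilt),

using the extrema-triangle construction: a marker sits on a wave crest or
trough when the planar angle it forms with its two neighbours is at a
temporal minimum; extrema are chained across markers, linearly interpolated
in time, and every frame with two same-type extrema bracketing an opposite
one contributes λ = |P₁P₂|, σ = the signed tilt of the triangle's median
from the base perpendicular, and A = |median|·cos σ.

Downstream, log–log scaling of morphometric and kinematic traits against
snout–vent length (SVL) is analysed with AICc-ranked ANCOVA model search
(Type III tests, sum-to-zero coding), reduced-major-axis regression
(slope = sign(r)·s_y/s_x with the standard 95% CI) and isometry verdicts
(expected exponent 1 for linear traits, 3 for mass). Size-corrected
residuals feed Pearson correlations and a maximum-likelihood path analysis:
Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ is fitted to the residual correlation matrix by
minimising the Wishart discrepancy, with χ² lack-of-fit, RMSEA, AICc and
per-path likelihood-ratio tests.

## Worked example

```python
import numpy as np
from sidewinderkin import (WaveParams, TrialGroundTruth, generate_trajectory,
                           smooth_trial, extract_trial_kinematics)

wave = WaveParams(frequency_hz=0.3, wavelength_cm=20.0, amplitude_cm=10.0,
                  skew_deg=5.0, lift_height_cm=2.0, duty=0.25,
                  smooth_frac=0.04)
gt = TrialGroundTruth(wave=wave, n_frames=4500, noise_sd_cm=0.1, seed=11)
kin = extract_trial_kinematics(smooth_trial(generate_trajectory(gt)))
print(f"speed {kin.centroid_mean_speed:.2f} cm/s "
      f"(truth {gt.centroid_speed_cm_s:.2f})")
print(f"f {kin.frequency_hz:.3f} Hz  lambda {kin.wavelength_cm:.2f} cm  "
      f"A {kin.amplitude_cm:.2f} cm  skew {kin.skew_deg:+.2f} deg  "
      f"height {kin.height_lifted_mean:.2f} cm")
```

prints

```
speed 5.88 cm/s (truth 5.91)
f 0.300 Hz  lambda 19.99 cm  A 9.98 cm  skew +4.89 deg  height 2.05 cm
```

— the generated trial travels at 5.91 cm/s (frequency × stride, with stride
determined by the wave geometry), and the full pipeline (3-pass 4th-order
Savitzky–Golay smoothing at a 143-frame span, edge trimming, extrema
detection and triangle geometry) recovers every wave parameter to within a
few percent despite 1 mm digitizing noise.

The end-to-end pipeline also runs from the shell:

```bash
sidewinder-kin all --out results/ --seed 1
```

writing per-trial kinematics, scaling and ANCOVA reports, the handedness
summary and the path-model report as CSV/JSON.

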