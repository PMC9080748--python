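# Methods

## The synthetic sidewinding model

The generator treats steady sidewinding as a shape-invariant planar
travelling wave with static contact sections. The body's lateral profile
is a function g(ξ) of the body-axis coordinate ξ (cm), periodic with
wavelength λ; a body point with coordinate s sits at phase ξ = s + c·t
with wave speed c = f·λ. The template is a corner-smoothed skewed
triangle: troughs at multiples of λ, the crest offset from the midpoint by
A·tan σ (σ = skew angle, positive head-wards), straight legs joined by
quadratic C¹ blends of half-width w = `smooth_frac`·λ.

Two closed-form corrections make the template's *measured* extrema match
the nominal parameters exactly: blending lowers the peak-to-peak by
2wA/λ (the raw triangle amplitude is therefore A/(1−2w/λ)), and it shifts
the crest and trough apices in opposite directions, shrinking their
relative offset by (1−4w/λ) (the crest is constructed at
λ/2 + A·tan σ/(1−4w/λ)).

**Contact and stride are not free parameters.** The contact section is a
straight sub-segment (fraction `duty` of the cycle) of the trough-to-crest
leg. Requiring those material points to be exactly stationary in the
ground frame forces the whole wave pattern to translate rigidly
anti-parallel to that leg; by periodicity the net displacement per cycle is
then exactly perpendicular to the wave axis, with

    stride = λ · (contact-leg slope),   speed = f · stride.

`TrialGroundTruth.stride_cm` and `centroid_speed_cm_s` are derived
accordingly. Each marker moves on a straight line parallel to the travel
direction — the idealized sidewinding signature. The up-leg segments
outside the contact interval carry a small C¹ inward dip so that only the
contact fraction of a cycle is instantaneously stationary. The vertical
profile is z = H·sin²(π·τ) across the swing fraction, zero during contact,
C¹ at lift-off. Left-handed trials are exact mirror images (x → −x,
applied after noise so mirror pairs with equal seeds are bit-identical).
I.i.d. Gaussian positional noise is added last.

### Detector-consistent waveform calibration

The three-point extrema detector (below) evaluates a *chord* angle at
marker spacings of ≈0.39 λ. For a generic asymmetric waveform the temporal
minimum of that angle does not fall on the true extremum: on a sheared
sine the offset nearly cancels the shear (≈2 cm at 0.42 λ spacing),
collapsing the measured skew toward zero and biasing the amplitude low.
This is an O(spacing) property of the estimator itself, worth knowing when
interpreting skew measured from sparse markers.

Because any C¹ waveform satisfying the wave invariants is admissible, the
generator calibrates the swing-section shape so that the chord-angle
minimum falls exactly on each extremum: one antisymmetric compact bump per
apex is placed at the free flank point one marker-spacing away (outside
the contact band, vanishing at the apexes so the extremal geometry is
untouched) and its amplitude is solved so dθ/dφ = 0 at the apex. The
calibration is evaluated on the waveform *as the pipeline will see it*: a
zero-phase temporal filter acting on a travelling wave is exactly a
reweighting of spatial harmonic k by the filter gain at frequency k·f, so
the condition is imposed on the gain-reweighted template. The generated
trajectory itself is always the pure, unfiltered waveform. When the
geometry leaves no room for the bumps (large duty, extreme skew, flanks
landing on protected regions) the generator falls back to the plain
template with a warning that extracted amplitude and skew will carry the
secant bias.

### Study-grid conditions

`default_study_grid` fixes the synthetic study conditions once: cycle
frequencies 0.25–0.35 Hz, wavelengths 14–20 cm, peak-to-peak amplitudes
8–16 cm, skew angles −5…+5°, lift heights 2–3 cm, duty 0.25, 0.1 cm
digitizing noise, alternating handedness, bodies spanning ≈3 wavelengths.
These emulate slow, steady sidewinding — the lower end of observed speeds
(the grid's trials travel ≈5–12 cm/s) — and sit inside the band where the
configured smoothing filter (−3 dB near 2.3 Hz; shape information lives in
harmonics 2f–3f) resolves the waveform. At fast cycles (≳1 Hz) the same
filter attenuates the wave's shape harmonics strongly: amplitude reads
≈16% low and skew collapses at f = 1.5 Hz, and a lift pulse shorter than
the filter window is flattened. Passing recovery tests therefore
demonstrate correctness of the estimator within the temporal resolution of
the measurement chain, not robustness to under-resolved fast locomotion.
Real digitized data additionally contain marker dropouts, digitizing
jitter correlated across frames, non-steady behaviour (turns, stops,
head-raising) and body-length changes none of which the generator
emulates.

### Morphometrics

log₁₀(trait) = log₁₀ a + b·log₁₀ SVL + sex/age offsets + N(0, sd), with
isometric defaults (b = 1 linear, b = 3 mass) and intercepts giving a
40 cm snake realistic values (≈100 g, 2.6 cm mid-body width). Scale
counts are drawn as rounded normals with a sex offset (females more
ventrals, fewer subcaudals) and no SVL dependence.

## Pre-processing

Displacement is smoothed with a 3-pass 4th-order Savitzky–Golay filter,
uniform weights, 143-frame span at the 250 Hz working rate; velocity and
acceleration come from first/second-order central differences and one
further pass; 150 leading and 100 trailing frames are dropped. All counts
are `SmoothConfig` parameters with those defaults. Edge frames use a
truncated-window polynomial fit; they are discarded by the trim anyway.

## Kinematics extraction

* Travel direction = direction of net centroid displacement (trials are
  assumed steady and roughly straight). All waveform geometry is computed
  on the x–y projection; z is used only for height lifted, measured above
  each marker's own trial minimum (substrate height is unknown in general
  data).
* Extremum events: temporal local minima of the three-point planar angle,
  with a minimum prominence (default 5°) to suppress noise minima and a
  collinearity cutoff (no event above 170°). The crest/trough label comes
  from the sign of the planar cross product in head-to-tail marker order —
  a chiral label, which is why the raw skew sign is only valid for
  right-handed trials and `apply_handedness_sign` negates left-handed
  trials (annotated handedness is required; it cannot be inferred by this
  construction).
* Chaining (the nearest-in-phase heuristic): events of one kind join the
  open chain whose latest event came from a more head-ward marker within
  0.75 estimated periods per marker gap; chains of one event are dropped
  with a warning. Periods are pooled across markers and kinds before
  taking the median for the frequency (1/median period).
* The skew sign at each triangle: the median's lean along the body axis,
  referenced to the right-of-travel direction, with the apex's front/rear
  position relative to travel disambiguating the median's direction. Trial
  values average over every frame and triple where a complete
  same–opposite–same triple exists; otherwise the wave fields are NaN,
  never fabricated.
* The z-score marker band search minimises the mean of per-marker mean
  |z| over contiguous bands, preferring the longest band within 0.05 of
  the optimum so sampling noise cannot shrink the band to one lucky
  marker; the fixed bands 3–7 (peak speed) and 2–8 (height) are available
  as defaults.

## Scaling statistics

* Outlier rule: within each age class, log trait ~ log SVL + sex;
  standardized residuals; flag when |z| > 3 AND the point sits > 1 s.d.
  from the next most extreme residual (the conjunction is the conservative
  reading; an OR variant is a config switch). One pass only. An
  essentially perfect fit (residual scale < 1e−10) flags nothing rather
  than standardizing floating-point noise.
* ANCOVA search: the full SVL×sex×age interaction model and every
  marginality-respecting submodel (a main effect is never dropped while
  its interaction remains) are all fitted — the lattice is cheap — and
  ranked by AICc with k = coefficients + 1 (residual variance counted, the
  R convention). Body temperature, when included, enters additively only.
  Selection takes the lowest AICc except that among models within 2 AICc
  units of the best the one with the most predictors wins, favouring the
  granular view of group-specific scaling. Note the statistical
  consequence, which the recovery tests acknowledge: for any nested pair
  differing by one null term, ΔAICc = 2 − χ²₁ < 2 always, so this tie rule
  systematically admits richer models; predictor *retention* (the
  generating terms are kept) is the recoverable property, exact-set
  parsimony is not. Type III tests use sum-to-zero contrasts (Type III is
  contrast-dependent).
* RMA: slope = sign(r)·s_y/s_x through the means; 95% CI via
  B = t²₀.₀₂₅,ₙ₋₂(1−r²)/(n−2), CI = slope·(√(B+1) ± √B) — the standard
  formula for standard-major-axis intervals. Isometry verdict: allometric
  iff the expectation (1 or 3) falls outside the CI.
* Handedness: counts per category; among individuals with exactly three
  scored trials, the all-same proportion against the i.i.d. fair-coin
  expectation 2·(1/2)³ = 25%.

## Path analysis

Observed-variable models only (≤7 variables, complete cases): Σ(θ) =
(I−B)⁻¹Ψ(I−B)⁻ᵀ with one free parameter per path, per variance and per
declared error covariance. The Wishart ML discrepancy is minimised by
BFGS with an analytic gradient from a sample-moment start and seeded
jittered restarts (default 10; the problem is small and smooth, restarts
guard against local minima). χ² = (n−1)·F; standard errors from the
inverse expected (Fisher) information; RMSEA = √(max(χ²−df,0)/(df(n−1)));
per-path LRTs refit with the path pinned to zero (differences clipped at
0); AICc = χ² + 2k + 2k(k+1)/(n−k−1). The default input is the residual
*correlation* matrix, so squared coefficients read as variance explained;
covariance-matrix fitting is a flag.

The default seven-variable model: frequency, wavelength, amplitude and
skew carry paths into mean centroid speed, mid-body width into wavelength,
and height lifted enters through covariances only; covariances are free
among all exogenous pairs plus the wavelength residual with each
non-parent exogenous variable. That parameterization has
28 − 26 = 2 degrees of freedom. The 16-model menu is a reconstruction
shipped as a default: every 3-subset of {skew, height, tail, ventral
count, mass, mid-body width} joins the fixed core {speed, frequency,
wavelength, amplitude}, excluding subsets holding both stoutness measures
(mass and width) — exactly 16 seven-variable models. Menu comparison
rejects models with χ² lack-of-fit p < 0.05 and ranks survivors by RMSEA,
ties broken by AICc.

Limitations: no latent variables, no multi-group models, no full-
information treatment of missing data (complete cases only); n for each
model is its complete-case count.

## Problem sizes

The recovery suites run at deliberately modest sizes: 27 synthetic trials
of 4000–5500 frames for waveform recovery; 100 replicates at n = 200 for
ANCOVA retention, n = 500 for RMA coverage, and n = 2000 for path-model
recovery, scored on the path coefficients (the parameters of scientific
interest) within 3 standard errors.
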