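# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic study can
and cannot demonstrate.

## Protocol emulated

A 90-minute dynamic brain acquisition for a reversible tracer without a
reference region. The bolus is injected 30 s after the scanner starts, so
the frame schedule carries one 30-s pre-injection background frame; all
kinetic computation uses seconds post-injection, with the offset subtracted
once at load time. The default schedule has 27 frames (15-s early frames
lengthening to 600 s) whose edges land on every 10-min boundary from 15 min
onward, so SUV epochs and the 60/70/80-min truncation points are always
frame-aligned. Activity is decay-corrected to injection time on load
(F-18 half-life 109.77 min, configurable). Blood data comprise a continuous
whole-blood detector curve over 0–15 min (1-s resolution) and nine discrete
arterial samples between 5 and 90.5 min, each with whole-blood activity,
plasma activity and parent fraction.

## Input-function construction

1. **Cross-calibration.** The continuous detector has an unknown gain; a
   single multiplicative scalar is fitted by least squares over all discrete
   whole-blood samples falling inside the continuous window (linear
   interpolation of the detector curve at the sample times, ±5 s matching
   window). Negative detector readings are clamped to zero first and the
   count logged.
2. **Plasma conversion.** The plasma-over-blood ratio is linear between
   paired discrete samples and held constant beyond the first and last; the
   calibrated whole-blood curve is multiplied pointwise.
3. **Tail extension.** Past the continuous window the plasma curve follows
   a shape-preserving piecewise cubic (PCHIP) through the later discrete
   plasma samples, anchored at the continuous curve's end point. PCHIP was
   chosen over an unconstrained cubic spline because it cannot undershoot
   into negative activity between sparse late samples.
4. **Parent fraction.** A Hill-type decreasing sigmoid
   f(t) = 1 − A·tʰ/(tʰ + T₅₀ʰ), which satisfies f(0) = 1 by construction, is
   fitted to the discrete parent-fraction measurements by uniform-weight
   nonlinear least squares (bounds 0 ≤ A ≤ 1, T₅₀ > 0, 0.05 ≤ h ≤ 10;
   moment-based start values). Uniform weights are the simplest defensible
   choice given that metabolite-analysis error models are rarely reported.

The product of stages 1–4, resampled to a uniform 1-s grid from injection
to scan end and clamped at zero, is the parent-plasma input function
(ppIF). Each stage is scale-equivariant in activity, and the chain
reconstructs a noise-free generated input function to < 1% AUC error
(verified in the tests).

## Spectral analysis

Classic spectral analysis: the frame-averaged tissue curve is regressed,
by nonnegative least squares, onto basis functions
C_p ⊛ e^(−βⱼt) frame-averaged the same way, with 100 rates βⱼ log-spaced
between the slow and fast boundaries (0.000196–0.2 s⁻¹ for 90-min data).
V_T = Σ αⱼ/βⱼ over the tissue bases. Choices that matter:

- **Convolution.** Basis columns are computed on the input function's 1-s
  grid with an exact piecewise-linear recursion (an IIR filter pass per
  rate), then frame-averaged via the cumulative trapezoidal integral; both
  steps are exact for piecewise-linear curves, and the tests hold the
  result to < 0.1% of a dense-quadrature oracle.
- **Grid size.** 100 basis rates keep the grid-resolution error well below
  the 2% oracle tolerance on V_T; the boundaries, not the count, dominate.
- **Weights.** Frame-duration weights by default (uniform and
  duration/activity variants available) — longer frames carry more counts.
- **Vascular component.** An optional extra basis column carries the
  whole-blood curve (the input function stands in when whole blood is
  unavailable); its coefficient is excluded from V_T. It is on by default
  for voxel fits, since voxel signal contains a blood-volume fraction.
- **Units.** Rates are s⁻¹ internally; compartmental K₁/k's are accepted in
  conventional min⁻¹ and converted at the boundary.

Shortened acquisitions (60/70/80 min) reuse the full-length ppIF but
rebuild the basis with duration-specific slow boundaries
(0.000290/0.000256/0.000222 s⁻¹). These four boundary values follow no
derivable formula (their reciprocal time constants 3448/3906/4505/5100 s
fit no obvious rule), so they live in a lookup table with an explicit
override rather than behind a guessed formula.

## SUV

SUV = duration-weighted mean decay-corrected activity over a frame-aligned
epoch × body weight (g) / injected dose (Bq). Body-weight normalisation
(not lean mass or BSA) matches the covariate the PBIF normalisation uses.
Epochs that would split a frame are refused rather than interpolated.

## Population-based input functions

Standardisation: each training ppIF is scaled by the product of
median/value ratios of weight, injected dose and age (the three factors
commute, so the medians are computed once from the raw covariates; the age
factor reflects the cohort's age effect on tracer metabolism and can be
disabled); each curve's lightly smoothed (5-s moving average) peak is
shifted by whole 1-s steps to 80 s; the pointwise median across the cohort
is the standardised curve. Aligned curves are truncated to their common
support — tails are never padded by holding the last value — and the median
is then extended back to scan end with a log-linear tail fitted over its
last 300 s (alignment shaves at most a few tens of seconds from a
slowly-decaying tail, so this extension is benign; the choice is ours, as
the handling of unequal supports is genuinely open).

Individualisation: ordinary least squares of training-ppIF AUC on the
90-min parent-plasma concentration; the standardised curve is scaled by
predicted-AUC / standardised-AUC for the target's single anchor sample.
The protocol is leave-one-out by default (the target participant
contributes to neither the median nor the regression), switchable to
all-participants for small cohorts.

## Synthetic cohort

The generator supplies the study conditions and ground truth:

- **Cohort.** 20 participants; injected dose ~ N(187, 4²) MBq truncated
  positive; weight uniform 55–95 kg; ages stratified-uniform over 20–62 y;
  subgroups cycle through control / epilepsy / epilepsy-on-antidepressants
  in roughly 9:6:5 proportions.
- **Whole blood.** Gamma-variate first pass (peak drawn 45–75 s) plus a
  two-exponential tail (time constants 20 and 150 min) with a smooth onset;
  amplitude scales with dose/weight. The plasma-over-blood ratio rises
  linearly from 1.0 to ~1.16 at 90.5 min. The continuous detector applies a
  uniform(0.8, 1.2) gain that cross-calibration must recover.
- **Parent fraction.** The Hill sigmoid above with A ≈ 0.82, h ≈ 1.5 and
  log T₅₀ carrying a −0.30 loading on standardised age against residual sd
  0.33, giving a cohort correlation of about −0.66 between age and
  parent-fraction AUC in expectation (older participants metabolise
  faster).
- **Tissue kinetics.** Two-tissue compartment forward model with fractional
  blood volume: C_voxel = (1 − v_b)·(h ⊛ C_p) + v_b·C_wb. Shared rate
  constants k₂ = 0.12, k₃ = 0.05, k₄ = 0.02 min⁻¹, v_b = 0.05; per-ROI K₁
  set so the seven analysis regions hit V_T targets of 9.9–12.7 (the
  bilateral cerebellar, hippocampal, occipital, parahippocampal, putaminal,
  superior-frontal and thalamic values of the emulated protocol's reference
  table; the eighth named region, the occipito-temporal gyri, is excluded
  from the default analysis set to match that table's seven rows). These
  rates put the slow kinetic eigenvalue at ≈ 2.3 × 10⁻⁴ s⁻¹ — inside the
  90-min spectral window but below the shortened-scan slow boundaries — so
  truncation bias arises from the physiology, not from tuning.
  A participant-level lognormal factor (sd 0.22) on K₁ produces ~22%
  between-subject V_T spread, plus subgroup multipliers (0.88 epilepsy,
  1.05 epilepsy-on-antidepressants; free parameters of the design, not
  calibrated to any reported effect size).
- **Noise.** Multiplicative Gaussian (2%) on blood samples, additive
  (1.5%) on parent fractions, and frame-level Gaussian noise with
  sd = 50·√(activity/frame duration) on voxels — a count-statistics proxy
  giving ~4% noise on late 600-s frames and ~9% on early 15-s frames.
- **Phantom.** Disjoint labelled blocks (default 12³ volume, 64 voxels per
  region) standing in for an anatomical parcellation.

Every generator is deterministic given its seed; the pipeline derives
per-participant substreams from the study seed.

**What the synthetic study does not show.** No scanner PSF, attenuation,
scatter, randoms, reconstruction artefacts, motion, or anatomically
realistic mixing of tissue classes; the between-subject structure is a
single multiplicative kinetic factor. Consequently blood-free SUVs
correlate with V_T more uniformly across epochs here than they do in real
cohorts, where flow and peripheral-clearance heterogeneity degrade early
epochs; and absolute agreement numbers from this cohort characterise the
pipeline, not any real tracer population. The direction-of-effect findings
(truncation underestimates V_T monotonically; single-sample PBIFs preserve
ranking but inflate BS-CV) are the transportable conclusions.

## Problem sizes and tolerances

The default study is 20 participants × 7 single-block ROIs on a 12³
phantom (448 fitted voxels per variant and participant), which keeps a
six-variant study to well under a minute of CPU. Oracle tolerances used in
the tests: spectral V_T within 2% of the compartmental closed form on
noise-free 90-min data; input-function reconstruction within 1% AUC
(3% pointwise after the first minute); convolution within 0.1% of dense
quadrature. Degenerate inputs fail loudly: mid-frame epochs or truncation
times, monotone curves with no interior peak, zero anchor variance in the
PBIF regression, irreversible kinetics (k₃ > 0, k₄ = 0) in the closed-form
V_T, and empty ROIs are reported as missing rather than zero.
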