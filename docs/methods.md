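# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind each module. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Image model and straightening

An axon is represented as a polyline path in pixel coordinates (0-based,
pixel-center convention), traced from the somatic domain through the
structure of interest into the distal axon. Straightening resamples the
path at 1-pixel arclength spacing and samples the image bilinearly at
offsets of up to ±`half_width` along the local normal (default half-width
0.63 µm = 3 pixels at the default 0.21 µm/pixel). The arclength position of
straightened column *i* is `i · pixel_size` from the trace start, so the
straightened width preserves the polyline arclength to within one pixel —
a property the test suite checks on quarter-circle paths.

The transverse band is collapsed per column by the **maximum** (default);
the maximum is robust to small transverse offsets between the trace and
the fluorescent ridge, which is the dominant tracing error in practice.
Mean aggregation is available. Normalization per channel maps
[baseline, max] → [0, 1], where the baseline is the **1st percentile** of
the column aggregate — a robust minimum under noise. Channels without
contrast are flagged `no-signal` and refused downstream, never silently
normalized. 3D stacks are maximum-intensity projected over z before
straightening.

## Extent rule and its bias model

The AIS/node extent on the normalized profile is first-above to last-above
a threshold fraction (default 0.40). Lengths use the inclusive pixel count,
`(end − start + 1) · pixel_size`, so a single suprathreshold pixel is one
pixel long; with continuous edge positions uniformly distributed over the
pixel phase this convention is unbiased in expectation. Sub-threshold gaps
between the first and last crossing are bridged (single-object assumption);
`strict_fragmentation` flags fragmented profiles instead.

For plateau objects with smooth edges the rule has a deterministic bias: an
erf edge of Gaussian width σ crosses the normalized level *f* at
`√2·erfinv(1 − 2f)·σ` outside the half-maximum point, so thresholds below
0.5 over-measure by twice that per object (`predicted_edge_bias`). At the
generator defaults (10–90% edge rise 0.5 µm, PSF σ 0.10 µm, f = 0.40) the
predicted bias is ≈ +0.10 µm — half a pixel — and the measured bias on
rendered populations agrees; the acceptance suite verifies recovered
condition means against target-plus-predicted-bias. The bias cancels
exactly in between-condition differences measured with the same settings.

## Synthetic data generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions of the analyses it feeds.

* **Geometry.** Axon paths are gentle sinusoids (amplitude 1 µm,
  wavelength 30 µm, random phase) so straightening is always exercised on
  curved traces; AIS onset distance ~ U(2, 5) µm from the trace start; the
  trace extends 5 µm past the distal end, as the extent rule requires.
* **Optics and noise.** Fluorescence is stamped along the path (the
  longitudinal plateau model evaluated at pixel-center arclengths),
  convolved with a Gaussian PSF of σ 0.10 µm (≈ 230 nm FWHM, a
  high-NA confocal), then corrupted with additive Gaussian noise of SD 3%
  of the plateau–background contrast. A Poisson noise option exists.
* **Condition populations.** Per-AIS true lengths are
  `mean + OTC offset + per-AIS normal noise`; the between-OTC SD defaults
  to 0 (per-condition statistics are specified as a single mean ± SD) and
  is exposed as a parameter. Draws are clipped at 1 µm with a warning if
  clipping touches more than 1% of them. Reference condition parameters
  (e.g. control 27.9 ± 3.0 µm; NMDA-block 32.1 ± 2.4 µm; chronic KCl
  27.0 ± 2.7 µm) are collected in `PLASTICITY_CONDITIONS`.
* **STED profiles.** `envelope × (1 + m·cos(2πx/T))` with T = 190 nm,
  plateau envelope, 2 µm region, and 10 nm sample spacing by default. The
  spacing is an assumption (acquisition pixel sizes at STED resolution are
  typically 10–20 nm); spacings coarser than T/4 are refused as
  undersampled.
* **Puncta.** Counts are Poisson (synaptopodin mean 3.3, vGAT mean 20.8
  per AIS in the reference groups); centers are placed uniformly inside
  the AIS extent with a 0.5 µm edge margin and a hard-core minimum
  spacing of 0.7 µm, because boutons and cisternal-organelle clusters are
  discrete ~0.5 µm objects that cannot coincide — a pure Poisson point
  process would place pairs closer than any physical separation and make
  the nominal count unrecoverable by *any* detector. The placed count is
  the manifest truth; placement truncation (extent too short for the
  drawn count) occurs in ~0.2% of draws at vGAT densities and is flagged.
  Puncta are Gaussian spots (σ 0.15 µm) on their own channel.
* **Electrophysiology.** A template-insertion leaky integrator: between
  spikes the membrane relaxes exponentially (τ 20 ms) toward
  `rest + I·R_in`; on reaching threshold, a stereotyped AP template is
  inserted and the integrator resets to rest. The template is a
  quarter-sine rise (duration hw/2) followed by a half-cosine fall
  (duration hw), which makes the width at threshold + amplitude/2 exactly
  the specified half-width and keeps the take-off sharp enough for dV/dt
  threshold detection. Traces are synthesized from exact analytic
  segments, so subthreshold steps obey Ohm's law at steady state to
  machine precision. This is deliberately not a conductance-based model:
  the analyses extract waveform features, not biophysics. Defaults: rest
  −65 mV, threshold −45 mV, amplitude 85 mV, half-width 1 ms, R_in
  150 MΩ, 20 kHz sampling, noiseless (noise SD exposed).
* **Longitudinal pairs.** Week-2 true lengths are drawn conditionally on
  week 1 with correlation 0.888 (chosen to match the reference
  week-to-week r² ≈ 0.789); both sessions share the axon path and onset,
  with length changes at the distal end.
* **Determinism.** All draws flow through one `numpy.random.Generator`;
  identical spec + seed give byte-identical arrays, and every emitted
  object has exactly one manifest record.

What the generator does **not** emulate: depth-dependent aberrations and
scattering of in vivo two-photon data, GRIN-lens distortion, axon
branching or varicosities, bleaching, sub-Poisson detector noise, and
motion. Passing recovery tests on these synthetics therefore demonstrates
correctness of the measurement pipeline, not robustness to every
real-world artifact.

## Autocorrelation estimator

Profiles are tiled into non-overlapping 2 µm windows; each window is mean-
subtracted and its **unbiased** sample autocorrelation
`r(k) = [Σ x_i·x_{i+k}/(N−k)] / [Σ x_i²/N]` is computed up to 400 nm and
averaged across windows, then across cells (resampling mismatched lag
grids onto the finest one). The unbiased form is used so that closed-form
anchors hold: a pure 190 nm cosine gives AC(190) = 1, AC(95) = −1, and
amplitude statistic 2. (The biased divide-by-N form would taper these to
≈ 0.905/−0.95 over a 2 µm window, destroying the closed form; its |r| ≤ 1
guarantee is given up, which is harmless below 400 nm lags on 2 µm
windows.) Values at the 95/190/285 nm anchor lags are linearly
interpolated between sample lags; at 10 nm spacing this carries a
quadratic error of up to `(2π·5/T)²/2 ≈ 0.014` at a cosine extremum,
which bounds the observed deviation of the pure-cosine amplitude statistic
from 2. Period detection takes the first local maximum after the first
local minimum and refines it by three-point parabolic interpolation;
curves without such a maximum are reported as aperiodic, not as a number.

## Puncta detection

Gaussian smoothing (σ 0.15 µm) → local maxima above
`median + k · MAD-based SD` (k = 3) with non-maximum suppression at
0.4 µm, optionally restricted to the measured extent. The background SD is
estimated from the **raw** channel and the threshold applied to the
smoothed image: smoothing correlates the noise, and thresholding at 3
post-smoothing SDs would admit one or two correlated-noise maxima per
image; referencing the raw-noise SD keeps the false-positive rate
effectively zero while leaving real puncta (an order of magnitude above
background) untouched. Median and MAD both scale with intensity, so
counts are invariant to global intensity scaling.

## Electrophysiological feature definitions

AP detection: peaks above 0 mV whose preceding 5 ms contains dV/dt ≥ the
criterion (default 20 mV/ms, config-exposed; the value is a common choice
for somatic recordings), with ≥ 1 ms separation; peaks without a complete
repolarization before the sweep end are excluded and flagged. Threshold is
the voltage at the first criterion crossing of the rising phase; amplitude
is peak − threshold (so threshold + amplitude equals the peak sample
exactly); half-width is measured at threshold + amplitude/2 with linear
interpolation between samples (a definition chosen over peak-to-rest
half-height and stated explicitly since conventions differ); maximal rise
is the largest dV/dt between threshold and peak. Waveform features come
from the first AP fired ≥ 30 ms after step onset; sweeps without such an
AP contribute none. Rheobase is the smallest step current with ≥ 1 AP
during the step, flagged when unreached or when the lowest step already
fires. Input resistance divides the steady-state deflection (mean over the
last quarter of the step) of the hyperpolarizing test sweep (−100 pA where
available) by the injected current.

## Statistical layer

* **Grubbs gate:** iterated single-removal two-sided Grubbs at α = 0.05,
  critical values computed from the t-distribution
  (`G = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{1−α/(2n), n−2}`) rather than a
  lookup table; calibration is verified by simulation in the tests.
* **Normality gate:** Shapiro–Wilk at α = 0.05 per group (the branching
  between parametric and nonparametric tests needs a concrete gate;
  groups too small to test, n < 3, are treated as normal). The gate can
  be overridden explicitly.
* **Branches:** two groups → (paired) t-test or Mann–Whitney; more → one-
  way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn. Dunn's z-tests use
  pooled mean ranks with tie correction and Bonferroni adjustment over
  all pairwise contrasts (an adjustment must be fixed; Bonferroni is the
  most conservative standard choice).
* **Longitudinal:** paired t-test on week differences plus OLS of week 2
  on week 1 with r²; zero-variance differences are flagged degenerate
  instead of producing a p-value.
* **Condition summaries:** the statistical unit is the per-OTC mean
  (n = number of cultures), matching how such experiments are powered;
  per-AIS pooling is available but non-default. Tables report mean,
  median, and SD. Conditions with a single unit are summarized but
  excluded from comparisons.

## Problem sizes and numerical choices

Figure-level replications and the acceptance script use the study-scale
cohort sizes (6 OTC × 50 AIS per condition, 50 AIS puncta cohorts, 30
longitudinal pairs), repeated over 10 seeds in the acceptance script;
Monte-Carlo calibration checks (type-I rates, Grubbs level) use 10³–2×10⁴
replicates. Large-n statistical-fidelity checks of the generator (10⁴
draws) run on the placement/draw layer without rendering. Degenerate
inputs are explicit errors, never NaNs: zero-variance profiles
(autocorrelation), contrast-free channels (normalization), sub-Nyquist
STED spacing, polylines with repeated vertices, and Grubbs with n < 3 all
raise typed exceptions.

## Known limitations

* The extent rule is 1-D along the trace; strongly bent or overlapping
  axons that a single polyline cannot describe are out of scope.
* The bias model covers erf edges; real AIS onset shapes may be
  asymmetric, and the proximal/distal biases then differ.
* The puncta detector assumes roughly isotropic blob-like objects well
  above background; it is not a deconvolution and does not split merged
  objects closer than the suppression radius.
* The ephys generator's stereotyped template cannot produce
  depolarization block, adaptation, or bursting; rheobase in the model is
  set by the steady-state condition `rest + I·R_in > threshold`, so very
  slow ramp-to-threshold dynamics near rheobase are idealized.
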