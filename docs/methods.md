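# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, what the defaults mean, where the design was genuinely open
and what the synthetic data can and cannot demonstrate.

## Signal definition

An ROI is a square pixel window, default edge 45 px, in 0-based (row, col)
coordinates with a half-open extent — fixed conventions, stated so layouts
are reproducible across tools.  The per-ROI signal is the **arithmetic mean**
of each channel's pixels.  The mean (rather than the histogram mode or
median) is linear in pixel values, which matches the least-squares
assumptions of everything downstream; the histogram itself is exposed for
inspection and the mean recomputed from it agrees with the direct mean to
1e-9 (a tested invariant).

**Reflectance** is defined per channel as the ratio of the sample ROI mean to
the blank ROI mean.  This is the standard convention in image colorimetry:
dimensionless, exactly 1 for the blank against itself, and free of the
chamber's overall illumination level.  The reference is the blank *cuvette*
ROI (solvent-filled), not a white chamber wall, so cuvette-wall losses cancel.
An effective absorbance, −log10(reflectance), is exposed as an optional
transform; it is not the default signal because reflectance is what the
acquisition directly supports, but see "feature space" below.  Images are
used in their stored 8-bit sRGB values with no gamma linearisation or
white-balance correction: inside a closed, LED-lit chamber these corrections
would be unverifiable knobs rather than calibrations.

## Calibration

Univariate calibration fits `response = m·c + b` by OLS and quantifies
unknowns by inverse prediction.  R² is `1 − SSres/SStot` exactly; a design
with a single concentration level or constant responses raises instead of
returning a meaningless fit.

PLS1 is fitted by NIPALS on mean-centred data (the algorithm in the module
docstring).  Column autoscaling is available but off by default: the three
reflectance channels share one physical scale, and autoscaling would inflate
the quietest channel's noise.  The regression-vector form
`b = W(PᵀW)⁻¹q` and the sequential-deflation prediction route agree to 1e-9
(tested); with as many latent variables as the feature rank, PLS predictions
equal multiple-OLS predictions (tested to 1e-8 against a normal-equations
oracle).

**Latent-variable selection** uses leave-one-out cross-validation and takes
the smallest count whose RMSECV is within 5 % of the global minimum.  The
choice of rule was open; LOO is exactly reproducible (no random folds) and
the parsimony margin prevents chasing noise in the RMSECV curve.  On real
chamber images more components may be chosen than on the synthetic scenes,
where the channels are exactly co-linear in concentration.

**Feature space.** The calibration features were genuinely open.  The
workflow defaults to the effective-absorbance transform of the three
reflectances: the synthetic scenes (and, to first order, real transmission
photographs) follow Beer–Lambert attenuation, under which absorbance is
linear in concentration while reflectance is exponential, and a linear
latent-variable model should be fed the linear representation.  Reflectance
and reflectance-plus-raw-means (p = 6) remain selectable for data where the
log transform is inappropriate (e.g. reflectance near zero at high
concentration, where the transform amplifies noise).

Figures of merit: RMSEC on the calibration set, RMSEP and bias on a
validation set when supplied, relative error % as the mean absolute
percentage error against the reference concentrations (reported for both
sets), R² between predicted and reference.  Zero reference concentrations
are excluded from percentage errors with a warning.  Negative predicted
concentrations are reported unclipped and flagged as below-blank; clipping
would bias RMSEP and bias toward optimism.

## Validation statistics

* Recovery `(C1 − C2)/C3 × 100`, accepted in [80, 120] %.
* Precision as CV = SD/mean × 100 with the n−1 denominator (triplicate
  groups are the norm), accepted when **at most** 20 % — a dispersion bound;
  a floor on CV would be meaningless.
* LOD = 3.3 σ/m, LOQ = 10 σ/m, so LOQ/LOD = 10/3.3 identically.  σ may be
  the SD of ten blank measurements or of the lowest calibration level; when
  σ is already in concentration units, `slope_m = 1`.
* Regression diagnostics: significance by the regression ANOVA F with
  (1, n−2) df; homoscedasticity by the Breusch–Pagan LM test (statsmodels
  implementation); residual normality by Shapiro–Wilk (scipy
  implementation).  An exact fit reports F = ∞ with p = 0 rather than
  failing.  Both diagnostic tests hold their nominal 5 % size to within
  [0.03, 0.07] empirically (2000-replicate simulation, part of the suite).

## Method comparison

The variance-ratio F keeps the reference method's variance in the numerator
— no larger-variance reordering — so F < 1 simply means the reference was
noisier; equivalence only requires F below the upper critical value.  The
paired t test needs raw per-replicate differences; printed means and SDs
cannot reconstruct it, so t columns appear only when raw data are supplied.
Critical values are always computed quantiles (t at 95 %, df = 2 is 4.3027;
a commonly printed 4.31 is that quantile rounded).  Both zero SDs give
F = 1 by convention (identical degenerate precision); a zero denominator
with a positive numerator is an error, not infinity, because it usually
signals a transcription problem.  Regulatory compliance is strict
(`c < limit`, default 3.0 × 10⁻¹ mg mL⁻¹).

The packaged ten-sample comparison table reproduces its published per-sample
statistics from the printed means/SDs for the internally consistent rows
(e.g. A6 relative error 0.00 %, A7 relative error 7.69 % and F = 1.00, the
cross-sample maximum relative error 7.69 %, maxima 5.16 × 10⁻³ and
4.83 × 10⁻³ mg mL⁻¹).  Two published numbers are *not* reproducible from the
published table itself: the quoted concentration minima (7.00 × 10⁻⁴ /
7.33 × 10⁻⁴ mg mL⁻¹) skip the A6 row, whose printed value 5.00 × 10⁻⁴ is
smaller for both methods, and the A3 row's printed reference SD implies
F ≈ 173 rather than the printed 1.85.  The package computes extrema and F
from the rows as given and documents the discrepancy rather than silently
dropping data; the corresponding acceptance test is left failing by design.

## Factorial optimisation

The acquisition optimiser is a 2² full factorial in camera distance
(5–16 cm) and LED intensity (coded; the physical low anchor of the LED is
instrument-specific and supplied by the user, the high level ≈ 1124 lx) with
five centre points, responses being calibration relative error %.  Corners
are built in standard Yates order with centre runs last; a seeded
randomised execution order is emitted separately so the analysis table stays
in standard order.  Effects are corner-mean contrasts (equal to twice the
coded-model least-squares coefficients, a tested equivalence); with
unreplicated corners the effect standard error is `2·s_centre/√4` on
n_centre − 1 df, and curvature is the corner mean minus the centre mean.
Pareto ordering sorts |t| descending with alphabetical tie-break; the
half-normal plot uses plotting positions Φ⁻¹(0.5 + 0.5(i − ½)/m).
Desirability for a minimise-type response is linear, `(high − y)/(high −
low)` clipped to [0, 1].  Second-order (response-surface) modelling is out
of scope; with only first-order effects, the recommended settings are the
corner minimising the fitted response, not a hard-coded distance.

## Synthetic scenes

The generator emulates the nine-cuvette chamber photograph: a 3 × 3 grid
(100 px cells) whose cells are painted with the Beer–Lambert colour of their
assigned concentration, `mean_ch = blank_ch · 10^(−k_ch·c)`, blank near
white (245, 243, 240).  The apparent absorptivities default to
k = (4, 60, 25) mL mg⁻¹ for (R, G, B): a red dye absorbing near 504 nm loses
green hardest, so k_g > k_b > k_r gives the synthetic data the qualitative
structure of the real system, and k_g = 60 spans about one decade of green
transmittance over the six-level curve 2.00 × 10⁻⁴ – 2.00 × 10⁻² mg mL⁻¹.
These k values are free synthesis parameters, not measurements of the dye.
Noise is additive Gaussian per pixel and channel (default SD 2 counts, a
quiet consumer sensor in a closed chamber), then clipped to [0, 255] and
rounded to 8 bits; clipping/rounding bias is below half a count and
negligible against 45² = 2025-pixel ROI averaging.  All randomness flows
through explicit seeds.

What passing the synthetic end-to-end test shows: the pipeline wiring, the
estimator algebra and the noise propagation are correct — two in-range
unknowns are recovered well within 5 % relative error at noise SD 2.  What
it does not show: robustness to illumination gradients, focus, JPEG
artefacts, cuvette misplacement or dye-matrix interferences; real images
remain nonlinear in ways the Beer–Lambert rendering is not.

## Problem sizes

Defaults used by the test suite and the acceptance script: 300 × 300 px
scenes with nine 45-px ROIs; six calibration levels; 2000 replicates for
diagnostic size checks (n = 100 regressions, n = 50 normality samples);
200–500 replicates for power checks; 9-run factorial tables.  These sizes
give stable Monte-Carlo estimates (binomial SE ≈ 0.005 at 2000 replicates)
while keeping the whole suite in a few seconds.
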