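# Methods

This note documents the models, the synthetic ground truth, the numerical
choices, and the limitations of `v2lamina`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

### GLM

BOLD runs are modelled by ordinary least squares per voxel. The stimulus
regressor for a block is a boxcar convolved with a single-gamma impulse
response h(t) = (t/p)^q · exp(q − q·t/p) with p = 5 s, q = 4 (h peaks at 1
at t = p); the convolved response is normalised so its plateau equals 1,
making betas read directly in percent signal change at the block plateau.
This is a smooth, plateau-normalised stand-in for the block regressors of
standard fMRI packages; downstream results depend only on those two
properties, not on the exact waveform. Nuisance regressors are an
intercept plus Legendre polynomial drift per run (order 2 by default; the
generator plants no drift, so the drift columns only exercise the
estimator). Two modes exist: one regressor per condition (selectivity
analyses) and one regressor per block, all blocks of a run in a single
model (block-wise t patterns for decoding). Block-design timing must be a
whole number of TRs within 0.01 TR; the default design (24 s blocks, five
per condition, 16.8 s lead/trail fixation, TR 2.4 s) gives 114 volumes per
run. Per-voxel t statistics use the usual s²·cᵀ(XᵀX)⁻¹c variance.

### Depth handling

Depth runs 0 (white matter) → 1 (pial). The equi-volume depth of a point
at cumulative volume fraction α in a column with inner/outer area elements
A_in, A_out solves the linear-wedge volume equation and is strictly
increasing in α, reducing to ρ = α for flat cortex; the implementation
switches to the flat limit when |A_out − A_in| is at machine-precision
scale, keeping it continuous. Bins are half-open — deep [0, 0.33), middle
[0.33, 0.67), superficial [0.67, 1] — which resolves the printed
overlapping endpoints deterministically. Pial-vein removal excludes
exactly ⌈0.05·N⌉ columns per area (largest mean signal change over all
stimulus conditions vs baseline, averaged over the column's depths), ties
broken toward the smaller column id, and the exclusion propagates to all
depths of the column. Applying the quota per area (rather than jointly)
was an interpretation choice; it keeps each area's retained pool size
predictable for feature selection.

### Selectivity and stripes

Selectivity is always SI of ROI-averaged betas (never the average of
per-voxel SIs; a two-voxel counterexample in the tests pins the order).
Eccentricity bins are [0, 3), [3, 6), [6, 18] degrees. Stripe
segmentation operates on the columnar (depth-averaged)
color-minus-disparity differential map restricted to columns with mean
activation > 0: the map is z-scored across included V2 columns
(guaranteeing invariance to additive offsets), thresholded at ±z
(default z = 1), connected components become thin (positive) and thick
(negative) bands, and an unlabelled column becomes pale when its nearest
labelled neighbours along u on the two sides are one thin and one thick.
The original stripe ROIs were drawn manually; this deterministic
procedure replaces that step, with the threshold exposed as a knob and a
threshold-sweep test guarding that compartment SI orderings do not depend
on it.

### Test–retest reliability

The observed statistic is the Pearson correlation of two sessions'
columnar differential maps over V2. The null holds session 1 fixed and
simulates session 2: the spatial ACF of session-1 GLM residuals
(column-averaged, radially binned via FFT autocorrelation) is fitted by
least squares to a·exp(−r²/2b²) + (1−a)·exp(−r/c), and null maps with
exactly that ACF are produced by shaping white noise in the Fourier
domain (the spectrum is the FFT of the ACF image, clipped at 0). The
volumetric simulation machinery of the reference workflow is replaced by
this sheet-level equivalent — same statistical contract, no external
dependency — and the surface-projection step becomes an identity on the
sheet (a fidelity gap worth naming: real pipelines correlate after
projecting simulated volumes through the surface). p-values are one-sided
with add-one smoothing, so p ≥ 1/(n_iter + 1) always. A practical
caution from the white-noise-convolution algebra: smoothing white noise
with a Gaussian kernel of scale σ_k yields an ACF of scale √2·σ_k, so a
fitted b should be compared against √2·σ_k, not σ_k.

### Informational connectivity

Per node (area × depth bin) and contrast: per-run per-block GLMs give one
t-pattern per block; per fold (leave one run out), feature selection uses
only training-run statistics — the per-run visual t (both conditions vs
baseline) and differential t (condition A − B) averaged over training
runs; stage 1 keeps ⌈0.2·N⌉ voxels by visual t, stage 2 takes 200 voxels
from each tail of the differential-t distribution (high tail first, low
tail from the remainder; ties toward smaller index). Patterns are
L2-normalised, a linear max-margin classifier (C = 1, tol = 1e−6) is
trained on the training blocks, and the geometric signed distance
(w·x + b)/‖w‖ is recorded for each held-out block.

Correlating raw distance series would be confounded twice, and the
implementation removes both confounds by centring:

1. **Design profile.** The per-block estimation variance of the block-wise
   GLM varies deterministically with block position (edge blocks, drift
   collinearity), identically in every region; through the normalised
   patterns this imprints a common distance profile that masquerades as
   connectivity. Because the profile is identical across folds, removing
   each (within-run block position, condition) cell mean across folds
   cancels it exactly while leaving block-level response fluctuations
   intact. (When a cell holds fewer than two folds this step is skipped.)
2. **Stimulus drive.** Within each fold, distances are centred per
   condition, so the correlation reflects block-to-block co-fluctuation,
   not the shared stimulus sequence.

The fold correlations are then averaged arithmetically (Fisher z enters
only at group level, matching the convention of averaging the raw
coefficients). A config switch (`concatenate_folds`) exposes the
alternative single-correlation-over-all-folds estimator; it is off by
default. Pathways: feedforward = (lower superficial, higher middle),
feedback = (deep, deep), over the adjacent pairs V1–V2, V2–V3ab, V2–V4;
group inference is a two-sided one-sample t on Fisher-z values with BH-FDR
across the full 18-cell family (3 pairs × 2 directions × 3 contrasts).

### Group statistics

One-way repeated-measures ANOVA uses the classical decomposition
F = MS_cond / MS_cond×subj, with a degenerate flag when the interaction
mean square vanishes; for k = 2 it equals the squared paired t (tested to
1e−10, and cross-checked against an independent implementation). The
compartment bootstrap resamples subjects with replacement (10,000 times by
default), takes per-compartment means and pairwise differences, and
reports two-sided add-one p-values against 0; vertex-level resampling is
available by passing a vertex × compartment table instead. Note the
percentile bootstrap is asymptotically calibrated but mildly liberal for
small cohorts (empirically ~8–10 % at n = 10 vs ~6 % at n = 200 under a
true null) — its unit calibration test therefore runs in the large-cohort
regime. Family-wise control for ANOVA families is Bonferroni, with post
hoc paired t-tests gated on the corrected ANOVA surviving (gatekeeping).

## The synthetic ground truth

Geometry is an abstract sheet, not a mesh: each area (V1, V2, V3ab, V4) is
a rectangular grid of cortical columns (60 × 50 at 1 mm spacing by
default) with three depth samples per column at volume fractions
{1/6, 1/2, 5/6}, converted to geometric depth via the equi-volume formula
under a sinusoidal curvature profile (A_out = 1 + 0.3·sin(2πu/30 mm)), so
curved cortex genuinely exercises the depth model. v = 0 is the V1–V2
border; stripes are periodic along u (8 mm thin/pale/thick/pale cycle,
duty 0.25 each) and constant along v; eccentricity rises linearly with
distance from the border row over 0–18°.

Planted response amplitudes (percent signal change, defaults in
`synthetic.default_truth`):

* V2 stripe amplitudes: thin (chr 2.6, ach 1.4; 3d 1.6, 2d 2.0), thick
  mirrored, pale neutral (2.0 everywhere) — thin stripes prefer color,
  thick prefer disparity, pale neither.
* Area amplitudes elsewhere, including texture (tex 2.2 vs noi 1.8 in V2,
  uniform across compartments — the no-texture-columns condition; a
  configurable null).
* Laminar structure: an overall depth gain (0.8 / 1.0 / 1.2) plus a pial
  vein gain 1 + 0.8·depth² and a 5 % subset of "vein" columns at 2.5×
  gain (what vein removal should catch). Depth-dependent *selectivity* is
  planted by multiplying the preferred condition only: ×1.6 superficial
  for color in V1/V2, ×1.6 deep for texture in V1/V2, nothing for
  disparity (flat profile).
* Texture eccentricity effect: preferred-condition amplitude
  × (1 + ecc/18).
* Block-level variability: every node's response in block b is scaled by
  m = 1 + w·s_b + jitter with jitter sd 0.15 and s_b a standard-normal
  latent shared within each coupled node pair; the default plants a
  single coupling, (V2 deep, V4 deep, texture, w = 0.8) — the feedback
  pathway the connectivity stage should (and does) single out.
* Noise: white Gaussian noise smoothed on the sheet (FWHM 2 mm,
  FWHM = σ·√(8 ln 2)), variance-corrected analytically to sd 4.0 %
  per TR, independent across areas, depth samples and timepoints.

The noise level deserves a word: 4 % per-TR noise against ~2–4 % response
amplitudes puts single-block t-patterns at modest SNR, which is the
realistic regime for 1 mm gradient-echo EPI and — importantly for the
connectivity model — keeps the L2-normalised decoding distance
approximately linear in the block modulation m. At much higher SNR the
normalised distance saturates toward sign(m) and pathway correlations
stop growing with the planted coupling weight; the weight-sweep
monotonicity check operates in the linear regime.

Reproducibility: one master seed per dataset; sub-streams are derived by
fixed integer tags per purpose × contrast × session × run × area, so any
run or stage can be regenerated in isolation, repeat sessions share all
static structure (stripes, veins, gains) while redrawing noise and block
latents, and identical configs are bit-identical end to end (tested at
the CSV-output level).

### What the generator does not emulate

No hemodynamic nonlinearity, motion, physiological noise, or
draining-vein spatial displacement (the vein bias is gain-only); no
surface geometry beyond per-column area elements; the reduced 4-run
protocol is the only heterogeneity across subjects (anatomy is shared, a
per-subject stripe phase is not). Passing recovery tests therefore shows
the *analysis* is correct and well-calibrated under its own assumptions —
not that those assumptions hold in real 7T data.

## Problem sizes

Defaults mirror the study protocol: ten subjects, six with ten runs and
four with four runs per experiment, three experiments of 2 × 5 blocks per
run. The recovery suite runs this cohort once (~1.5 min) and shares it
across tests. Calibration checks use scaled-down cohorts chosen for
statistical adequacy at desk scale: 24 × 16-column areas with 30-voxel
selection tails (the selection pool scales with the patch), 20 null
cohorts for the family-wise false-positive check, 1000 repeats × 1000
iterations for reliability type-I calibration, and the coupling sweep on
the ten-run protocol (fold correlations from four-run subjects are too
noisy for stable per-weight means). `scripts/acceptance.py` re-runs all
of it from a single seed.

## Known limitations

* The stripe segmentation replaces a manual step; at the reduced 4-run
  protocol its per-subject Dice against the planted map can dip to ~0.85
  for pale stripes even though cohort means stay ≥ 0.9 — the reduced
  protocol is genuinely noise-limited.
* The null-map simulator works on the periodic sheet grid; non-periodic
  boundary effects and surface projection are not modelled.
* The distance-centring steps (design profile, condition means) are
  required for null calibration but also discard any connectivity carried
  purely by condition-mean or block-position structure.
* Bayesian model comparison is out of scope; only classical statistics
  are produced.
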