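# Methods

This note documents what the package computes, the assumptions behind the
synthetic data, the parameter defaults that matter, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis pipeline

The pipeline reproduces a standard serum NMR metabolomics workflow for a
paired pre/post treatment design:

1. **Referencing.** Each CPMG-like spectrum is shift-referenced to the
   alanine methyl doublet. The detector considers local maxima inside a
   search window (default 1.3–1.7 ppm), pairs peaks whose spacing is
   doublet-like (0.5–2× the 7 Hz coupling at 400 MHz, ≈0.009–0.035 ppm)
   with comparable heights (ratio ≤ 3), and picks the pair whose midpoint
   lies closest to the target shift (default 1.48 ppm). This matters in
   serum: the lactate doublet (1.33 ppm) and the lipid CH₂ resonance
   (1.30 ppm) are far stronger than alanine and would otherwise hijack a
   naive "most prominent pair" rule. A spectrum with no peak above the
   prominence floor (5% of the window's dynamic range by default) is
   passed through unshifted with a failure flag.
2. **Bucketing.** Intensities are summed into half-open buckets
   `(low, high]` descending in ppm, anchored at the upper bound 9.0 and
   0.002 ppm wide — 4250 buckets over 9.0–0.5 ppm. Anchoring at the
   stated upper bound makes bucket counts deterministic; the sum of all
   buckets equals the raw intensity sum over the grid range
   (conservation, tested).
3. **Water exclusion.** Buckets whose *center* lies in the closed window
   4.38–5.15 ppm (width 0.77 ppm) are masked: 385 removed, 3865 retained.
   Exclusion by center is the simplest rule consistent with removing a
   region, and it commutes with raw-axis exclusion for edge-aligned
   windows (tested).
4. **No normalization.** There is deliberately no probabilistic-quotient
   or integral normalization step between bucketing and scaling.
5. **Pareto scaling.** Columns are mean-centered and divided by the square
   root of the sample standard deviation (n−1 denominator); zero-variance
   columns become zero. External test samples are transformed with the
   *training* statistics (`ParetoScaler`).

## OPLS-DA

The fit is NIPALS-style and deterministic (weights initialised from the
y-covariance; with a single binary response the inner loop converges in
one pass; tolerance 1e-10, cap 1000 iterations). Each orthogonal
component removes X-variation uncorrelated with class before a final
predictive component is extracted; with zero orthogonal components the
model is exactly single-component PLS1, which the test suite verifies
against an independent textbook implementation to < 1e-8.

Choices an implementer must fix that are fixed here:

- **Class coding** 0/1 over sorted labels, decision threshold 0.5 on the
  predicted response; label-swap symmetry of Q² is tested.
- **Orthogonal components** default to 2.
- **Cross-validation** is 7-fold with deterministic interleaved fold
  assignment over the sample order; if a training split would lose a
  class, folds are reassigned by within-class interleaving (logged).
  A training split with X'y = 0 (no class-correlated variation, e.g.
  perfectly symmetric duplicated rows) falls back to predicting the
  training class mean, so the symmetric degenerate case yields Q² = 0
  rather than an error.
- **Permutation testing** permutes labels (default 999 permutations, 199
  in the pipeline/acceptance defaults for runtime), refits the model and
  recomputes Q² per permutation, and reports
  p = (1 + #{perm ≥ observed}) / (n_perm + 1) for both R²Y and Q²; a seed
  is mandatory. Calibration is tested: under the null the p-values are
  uniform (KS over 200 replicates) and Q² is non-positive in expectation.
- **CV-ANOVA** follows the published formulation for cross-validated
  residuals in PLS/OPLS: SSreg = SStot − PRESS with DFreg = A (number of
  components, predictive + orthogonal), DFres = N − 1 − A,
  F = (SSreg/DFreg)/(PRESS/DFres), upper-tail p from the F distribution.
  A model no better than the mean gives F ≤ 0 and p = 1.
- **p(corr)** is the Pearson correlation of each centered variable with
  t[1]; zero-variance variables get 0 by convention, flagged.

## Quantification

Integrals use the "sum all points in region" rule over closed ppm
intervals. Panel regions (three lipid signals at 0.9/1.3/5.3 ppm; the
alanine doublet at 1.48; NAG at 2.07; ten glucose regions at 3.24–3.90
and 5.20 ppm) are configuration, with half-widths defaulting to ±0.01 ppm
for small metabolites (±0.012 for the alanine doublet so both lines are
covered) and ±0.05 ppm for the broad lipid signals; the exact boundaries
used by practitioners are lab-specific, so these are stated, overridable
assumptions. Lipids are quantified on the diffusion-edited-like channel,
small metabolites on the CPMG-like channel. Glucose is reported
per-region (the regions are columns; averaging is left to the caller).
An empty region raises a distinct error rather than returning zero.

## Responder stratification

Orientation is normalised so the post-treatment class mean score is
positive. Red = post sample at t[1] < 0; Green = pre sample at t[1] > 0
and not Red (Red precedence, since a patient could in principle satisfy
both); Grey otherwise. The boundary t[1] = 0 is the model's class
boundary — the only reproducible reading of a visual "origin cloud".
Trajectory distance is |t_post − t_pre|; a trajectory is "correct" when
it runs pre → post left to right.

The univariate battery uses average ranks for ties; the signed-rank test
uses the exact null for n ≤ 25 where possible and the
continuity-corrected normal approximation otherwise, with zero
differences split (so identical pre/post data give p = 1 rather than an
error). No multiple-testing correction is applied, matching common
practice for this design; this is a documented limitation, and the
retention filter for response correlations (|R| > 0.3 and p < 0.05)
provides the only guard. Note the signed-rank test is invariant under
positive affine transforms of the data but not under general monotone
transforms (it ranks difference magnitudes); the unpaired rank tests are
fully monotone-invariant.

## The synthetic cohort generator

The generator emulates the *statistical structure* of a paired serum
study, not acquisition physics: no pulse sequences, relaxation, phase
errors, 2D JRES tilting, or lipoprotein-subclass structure. Spectra are
sums of unit-area Lorentzian lines (the physical default for solution
NMR; half-widths 0.0035–0.02 ppm by signal) on a 16384-point descending
axis over 9.3–0.2 ppm, plus a broad Gaussian baseline hump and white
noise. The alanine methyl signal is a 7 Hz doublet; other multiplets are
collapsed to singlets. Two channels per sample: CPMG-like (all
metabolites) and diffusion-edited-like (only lipid signals, 2× broader).
Five background metabolites (lactate, creatinine, citrate, formate,
histidine) carry no treatment effect but make referencing and bucketing
realistically hard. Concentrations are in arbitrary units — the pipeline
is scale-covariant up to Pareto scaling, so no absolute scale is needed.

Planted structure and defaults:

- **Treatment effect** (post/pre multipliers): lipids ×1.028 / ×1.094 /
  ×1.080 (0.9/1.3/5.3 ppm), NAG ×0.910, derived from the observed
  between-class median ratios of the reference analysis; glucose ×0.97
  and alanine ×0.96 as small common decreases.
- **Sex structure**: males carry *pre-treatment* elevations of glucose
  (×1.10) and alanine (×1.15) that are not re-applied post, so post
  levels converge across sexes and the glucose/alanine decrease is
  male-driven — reproducing both the cohort-level decrease and its
  male-only significance.
- **Subgroups**: full responders (proportion 34/53), weak_A ("Red"-like,
  10/53) with the effect attenuated to 0.15 on the log scale, and weak_B
  ("Green"-like, 9/53) equally attenuated but starting with 0.8 of the
  full effect profile already in place at baseline (visibly: elevated
  lipids, lowered alanine) and a planted lower initial nodal stage.
- **Variability**: between-patient biological log-SD 0.04, per-response
  log-SD 0.03, spectral noise SD 1.0 per point, calibration jitter
  0.002 ppm. These are not published quantities; they were chosen once,
  by a power analysis of the planted-structure recovery, so that the
  score plot shows a clear separation with a visible mixing cloud and the
  planted strata are recoverable. Real serum cohorts vary considerably
  more between subjects; passing recovery tests here demonstrates the
  pipeline's correctness, not that real cohorts of this size yield this
  recovery rate.
- **Clinical coupling**: male regression percentages are generated from
  the patient's planted lipid-1.3 log-change (slope 380 per log unit,
  noise SD 8); female regression is independent noise (median 78,
  SD 13). Tumour volumes are back-computed from the regression so the
  published regression formula recovers it exactly. Stage re-grading
  (yT/yN) is thresholded on regression with small randomness.

One master seed drives everything; per-patient substreams are spawned
with fixed offsets (`SeedSequence([seed, patient, stream])`), so cohorts
are reproducible under subsetting and regeneration is bit-identical.

## Clinical conventions

TNM v7 prefixes: "c" = pre-treatment clinical stage, "y" = post-treatment
re-stage. Sub-stages (2a/2b/2c) order within the same major stage and
stage differences are computed on the major numeric component (how
sub-stages should be differenced is not standardised; this is a stated
assumption). Tumour regression = 100 − post·100/pre, undefined for
pre = 0, negative for progression. Summary percentages are half-up
rounded to one decimal; stage groups III/IVa/IVb are reported
individually and combined as IV.

## Problem sizes

Defaults were chosen so the whole test suite and the acceptance script
each run in well under a minute of compute per heavy step: acceptance
uses a 53-pair cohort (16384-point spectra), 199 permutations, a
24-sample external test set, 200 calibration replicates at 24×40 and 500
null replicates for the correlation filter. All sizes are parameters.

## Known limitations

- The generator's between-subject variability is optimistic relative to
  real serum cohorts (see above); effect-size recovery rates do not
  transfer to real data.
- Lipid signals are single Lorentzians, not lipoprotein envelopes; the
  diffusion-edited channel is a stylised surrogate, and the CPMG-like
  channel stands in for JRES 1D projections.
- No phasing, baseline correction or apodization: the pipeline assumes
  already-phased real spectra exported from the spectrometer software.
- Only two-class OPLS-DA is implemented (no multi-class, no O2-PLS, no
  VIP scores).
- The CV-ANOVA degrees of freedom follow the simple component-count
  convention; commercial implementations use fractional df, so p-values
  can differ slightly for small models.
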