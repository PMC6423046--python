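# Methods

## Scope and model

`urimet` reproduces a urine ¹H-NMR diagnostic workflow for colorectal
neoplasia as a reusable library. The statistical core is a single-response
OPLS-DA model over a binned, reference-normalized, Pareto-scaled spectral
matrix, with blinded-holdout validation, STOCSY marker identification and
a diagnostic-accuracy panel. Because no real spectra are distributed with
the package, a first-class synthetic-cohort generator supplies inputs with
the statistical structure the analysis assumes; all data-dependent claims
are therefore properties checked on simulations, while the accuracy-panel
arithmetic is exact and checked against published counts.

## Synthetic spectra

Each spectrum is a sum of metabolite signals on a linear ppm axis
(defaults 0.0–9.5 ppm, 16 384 points, 500 MHz):

* **Lineshape.** Every resonance line is a unit-area Lorentzian with
  half-width at half-maximum `linewidth_hz / field_MHz` ppm (default
  1 Hz / 500 MHz = 0.002 ppm). A Lorentzian is the natural choice for a
  well-shimmed 1D spectrum; no lineshape was prescribed, so this is a
  simulator design decision.
* **Multiplets.** First-order patterns with a single coupling constant
  (default J = 7 Hz): singlet; doublet at ±J/2; 1:2:1 triplet spaced J;
  and "m" rendered as a binomial 1:4:6:4:1 quintet spaced J — a simple,
  symmetric stand-in for the many real higher-order patterns. Line weights
  sum to one per multiplet.
* **Marker library.** Eleven urinary metabolites with their literature
  chemical shifts and multiplicities; five increase in cases
  (3-aminoisobutyrate 1.18 d, alanine 1.48 d, taurine 3.27/3.45 t, urea
  5.80 s, valine 0.99 d) and six decrease (ascorbate, citrate, creatinine,
  glycerol, hippurate, threonine). Base concentrations are rough urinary
  orders of magnitude (creatinine and citrate large); only ratios matter
  downstream because of reference normalization and per-bin scaling.
* **Nuisance structure.** A TSP reference singlet at 0.00 ppm with fixed
  concentration 1.0; a broad Gaussian water hump (center 4.9 ppm,
  σ = 0.12 ppm, default amplitude 50) entirely inside the excluded
  4.6–5.2 ppm window and independent of class, so it exercises the
  exclusion logic; additive white Gaussian noise (default SD 0.005);
  and one multiplicative log-normal dilution factor per subject (default
  log-SD 0.3, i.e. roughly ±35% urinary concentration swings) applied to
  all metabolite signals but **not** to TSP or water — this is exactly the
  nuisance that TSP normalization is meant to remove.
* **Cohorts.** Default design mirrors the study population: 156 controls
  and 92 cases. Case concentrations are the control mean multiplied
  (direction up) or divided (direction down) by `fold_change`. The real
  marker effect sizes were never published, so `fold_change` is a free
  parameter; its default of 2.0 is a moderate metabolomics effect chosen
  once. Within-group biological variation is a mean-preserving log-normal
  with CV 0.2 per metabolite per subject (typical biological CVs for
  urinary metabolites run 15–50%). All randomness flows from one
  `numpy` Generator seeded by `SimConfig.seed`; identical configuration
  gives bit-identical cohorts.

What the simulator does **not** emulate: pH-dependent chemical-shift
drift, peak overlap from the hundreds of minor urinary metabolites,
baseline and phase artifacts, and between-run referencing error.
Consequently, passing tests demonstrate the correctness and statistical
behavior of the pipeline — not the clinical performance of the markers on
real urine, which depends on effect sizes that were never published.

## Preprocessing

* **Reference normalization** divides each spectrum by the trapezoidal
  integral over the TSP window (default ±0.05 ppm around 0, intersected
  with the axis since the default axis starts at 0 ppm). Integral rather
  than peak height is used: it is robust to linewidth variation. A
  non-positive reference integral is an error naming the sample.
* **Binning** lays half-open `[left, right)` buckets of width 0.0092 ppm
  from the high-ppm end downward; the single point at exactly `ppm_max`
  joins the first bin and a trailing partial bin at `ppm_min` is kept.
  The grid anchor was unspecified in the original protocol; anchoring at
  `ppm_max` is deterministic and axis-independent. Bin values are **sums**
  of point intensities (preserving integral proportionality; a mean would
  differ only by a constant per full bin). Any bin overlapping the
  4.6–5.2 ppm water window is dropped entirely rather than truncated —
  conservative removal of water distortion.
* **Pareto scaling** transforms each column to `(x − mean)/sqrt(sd)` with
  the sample standard deviation (denominator n − 1, the SIMCA
  convention). Zero-variance columns map to zeros and are kept so bin
  bookkeeping stays aligned. Training-set parameters are stored and
  re-applied verbatim to holdout or new samples — never re-estimated.

## OPLS-DA

Single-response NIPALS with sequential orthogonal deflation: for each of
K rounds compute `w ∝ Xᵀy` (unit norm), `t = Xw`, `p = Xᵀt/(tᵀt)`,
`w_o = p − (wᵀp)w` (unit norm), `t_o = Xw_o`, `p_o = Xᵀt_o/(t_oᵀt_o)`,
deflate `X ← X − t_o p_oᵀ`; after K rounds the predictive component
`(w, t_p, p_p, q)` is taken from the deflated matrix. With K = 0 this
reduces exactly to one-component PLS1, which the tests verify against an
independent implementation to 1e−8. Class labels are encoded 0/1 and
centered internally with the mean stored, so predictions return on the
0/1 scale and the a-priori cut-off 0.5 is meaningful; ties at the cut-off
classify as case (deterministic and documented). The default K = 3
matches the published score plots (one predictive + three orthogonal
components).

* **R²Y** is `1 − Σ(y − ŷ)²/Σ(y − ȳ)²` on training data.
* **Q²** is `1 − PRESS/SS` over stratified, seeded k-fold
  cross-validation; 7 folds by default (the SIMCA default; the original
  fold count was not stated). Folds are built by dealing shuffled
  within-class indices round-robin; a training partition missing a class
  triggers a warning and a reshuffle, an error after 10 attempts.
* **Holdout validation** takes a stratified blinded third per class —
  `floor(n_class/3)`, which reproduces the published 104/52 control and
  62/30 case partition — estimates scaling on the training part only,
  fits, predicts the holdout at the cut-off and reports per-class
  correct/total counts. The protocol's "three-fold cross-validation" is
  read as this single literal one-third holdout (the published partition
  counts confirm one split); the fraction is configurable and repeated
  splitting can be had by varying the seed.
* `fit_opls` rejects constant responses and `n_orth ≥ rank(X)`.

## STOCSY

`run_stocsy` computes, per bin, the covariance (denominator n − 1,
consistent with scaling) and Pearson correlation with a driver variable.
The driver defaults to the OPLS predictive score `t_p` — reading the
"correlation with the predictive component" coloring convention — and a
raw-bin driver gives classical STOCSY. Constant bins get correlation 0 by
convention and are flagged. Annotation matches bins with `|r| ≥ 0.6` (a
conventional strong-correlation cut, far above the ≈0.4 Bonferroni
significance bound at n ≈ 100 and ~10³ bins) to signatures whose peak
center lies within 0.02 ppm of the bin center (≈ two bins: bin width plus
lineshape spread); qualifying bins matching nothing are reported
unassigned. Per-metabolite group differences use the two-sided
Mann–Whitney rank-sum test (the original univariate test was unnamed;
rank-sum is the standard distribution-free choice for metabolite levels),
with direction from group medians.

## Diagnostics

Sensitivity, specificity, prevalence, PPV, NPV and likelihood ratios
follow the standard formulas (README). At specificity 1 the positive
likelihood ratio is reported as an explicit `"N/A"` sentinel rather than
infinity. Prevalence defaults to the evaluated set's composition and can
be overridden to project predictive values onto other populations.
ROC curves enumerate all distinct score thresholds (score ≥ threshold →
positive); the trapezoidal AUC then equals the Mann–Whitney pair-count
probability with ties counted one half, which a property test checks
exhaustively on small vectors and against scikit-learn. Multi-marker
ranking orients each metabolite's AUC to ≥ 0.5 and records the direction
(increased/decreased), sorting descending with a stable sort.

Metabolite levels are estimated transparently by summing normalized
intensity over ±0.02 ppm windows around every signature line — a
deliberate replacement for proprietary database fitting; it is linear in
concentration for isolated peaks but inherits baseline and overlap from
crowded regions.

**Rounding conventions.** Panel percentages are reported rounded half-up
to one decimal. The serum-marker panel (`marker_panel_from_counts`)
instead truncates to one decimal, matching the convention evident in its
reference values (2/32 = 6.25% reported as 6.2%, 155/156 = 99.359% as
99.3%). Two cells of the published reference accuracy table (stage-0 PPV
and advanced-adenoma NPV) are not reproducible from the published counts
under the published formulas — the exact values are 7/8 = 87.5% and
52/55 = 94.5% against printed 87.6% and 94.6% — and
`verify_reference_tables()` reports them honestly as mismatches; the
package's own outputs are always the formula values.

## Numerical choices and degenerate inputs

* Orthogonality of `t_p` to every orthogonal score holds algebraically;
  tests bound `|t_pᵀt_o|` by 1e−8 times the score norms.
* Deflation stops with an error if the orthogonal weight norm falls below
  1e−12 (orthogonal variation exhausted).
* Zero-variance bins: scaled to zero, correlation 0, never dropped.
* The empty reference window, non-positive reference integral, mismatched
  axes or dimensions, constant drivers/responses, and single-class label
  vectors all raise `ValueError` with the offending quantity named.

## Problem sizes

Tests run on reduced cohorts (20 + 20 samples, 4096-point axes) where the
full resolution adds nothing to the property being checked; the marker
recovery and permutation-null checks use 50 + 50 cohorts at full
16 384-point resolution and 200 label permutations. The full-scale study
replica (156 + 92 at 16 384 points) runs in seconds via
`urimet run`.

## Known limitations

* The simulator's clean multiplets and additive noise make classification
  easier than on real urine; holdout results near 100% on defaults
  reflect the chosen fold change of 2, not clinical performance.
* Window-integration levels are biased in crowded regions (e.g. the
  3.5–3.8 ppm glycerol/threonine/ascorbate overlap) — acceptable for
  ranking, not for absolute quantification.
* No peak alignment: real pH-driven shift drift would require alignment
  before binning, which is out of scope.
* Q² fold assignment is randomized per seed; SIMCA's exact deterministic
  grouping is unknown, so Q² values match published software only in
  distribution, not digit-for-digit.
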