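# Methods

## Model and procedure

cell-rPLR assigns every cell (i, j) of an n x d table of strictly positive
abundances an outlyingness value in [-1, 1], judged *relative to a
reference group* of samples. The pipeline is, for each feature pair (j, k):

1. **Pairwise log ratios.** `y_ijk = ln(x_ij) - ln(x_ik)`. Internally the
   difference-of-logs form is used rather than `ln(x_ij/x_ik)`: the two are
   equal up to one ulp, and the difference form makes the antisymmetry
   `y_ijk = -y_ikj` hold bit-for-bit (floating-point subtraction is exactly
   antisymmetric), which the implementation exploits by computing only
   pairs j < k and mirroring. Ratios cancel any per-sample multiplicative
   factor, which is the method's defining property: no normalization (TSN,
   PQN) is required, and the size-effect invariance is verified to 1e-10 in
   the tests.
2. **Robust standardization on the reference group.** The scale is
   `MAD = 1.483 * median|y - median(y)|` (the printed two-sided constant
   1.483 is used verbatim, not a higher-precision 1/Phi^-1(0.75)); the
   center is a *single* reweighting step from the median/MAD start: weights
   `v_i = omega_c((y_i - median)/MAD)` with Tukey's biweight
   `omega_c(u) = (1 - (u/c)^2)^2` on |u| < c (strict), c = 4.685, then
   `center = sum(v*y)/sum(v)`. No iteration is performed. Center and scale
   come from the majority group's rows only (ties between equally large
   groups break deterministically by first appearance, optionally by a
   seeded draw) and are applied to all n rows.
3. **Outlyingness function.** A bounded odd map `w* = (1 - omega(|u|)) *
   sgn(u)`, where omega is the Tukey biweight (default), Huber
   `min(1, k/|u|)` with k = 1.345, or Hampel with knots c1 = 1.6449,
   c2 = 1.9600, c3 = 2.3263 (the 0.95/0.975/0.99 normal quantiles rounded
   to four decimals, all overridable). The printed sign convention would
   give the adjusted Tukey the value 2 at u = 0; continuity and oddness
   force 0 there, which is what is implemented. The three families differ
   in their zero plateau (Tukey: the single point 0; Huber: [-k, k];
   Hampel: [-c1, c1]) and saturation (Tukey at |u| >= c, Hampel beyond c3,
   Huber only asymptotically) — this drives both the look of the heatmap
   and the detection behaviour discussed under Limitations.
4. **Aggregation.** `w_ij = median over k of w*_ijk`, including the
   identically zero diagonal term w*_ijj, following the aggregation rule as
   written; `include_diagonal=False` switches to the median over k != j
   (for even d the two differ by a known monotone shrinkage toward 0).
   Even-length medians are midpoints of the two central order statistics
   throughout.

Degenerate pairs (reference MAD = 0, possible with constant or heavily
tied columns) are flagged; their standardized values are 0 for
observations equal to the center and +-infinity otherwise, so the
outlyingness saturates at exactly +-1 in every family. The j = k column is
zero by definition and never flagged.

**Memory contract.** The conceptual n x d x d array is never materialized
by `transform`: slices over the nominator index are streamed, so working
memory is O(n*d) beyond the O(d^2) fitted centers/scales. At the scale of
a large untargeted study (44 x 2336) this runs in ~12 s and ~90 MB of
parameters, where the full array would need ~1.9 GB. An explicit
`outlyingness_array` accessor (guarded by an element budget, default 1e8)
exists for small problems and for tests.

**Estimator shape.** The computation splits naturally into learning the
per-pair reference statistics (`fit`, requires group labels) and applying
them (`transform`), so the package exposes scikit-learn estimators —
`CellRPLR` (transformer) and `RPLRBiomarker` (selector with
`get_support()` = features with permutation p <= alpha) — with the
procedure-style functions (`outlyingness_matrix`, `permutation_test`, ...)
as thin wrappers. This also means W can be computed for held-out samples
against a previously fitted reference.

## Biomarker identification (two groups)

`m_j = median(w_j in group 1) - median(w_j in group 2)`; the w are on a
common scale so m_j is comparable across features, and ranking by |m_j|
(default) or signed m_j orders candidates. Significance comes from a
permutation test run entirely on the aggregated W: each replicate shuffles
the feature index independently within each sample row, identically across
the denominator index — since one row-permutation applied to all slices
commutes with the median over k, this equals permuting the columns of W
within each row, which is what makes B = 1000 replicates cheap. The
permutation destroys the group structure (which enters through the
reference-group standardization) while preserving each sample's
outlyingness profile. The default p-value is the plain proportion
`(1/B) #{m_j <= m_j(b)}` (granularity 1/B, can be exactly 0); a
`(1+#)/(1+B)` correction is available. The printed estimator is one-sided
in the signed statistic; since a biomarker elevated in group 1 flips the
sign of m_j, the symmetric `|m_j| <= |m_j(b)|` version is the default for
discovery, with the signed version available. No multiplicity adjustment is
applied by default; `adjust="fdr_bh"` enables Benjamini-Hochberg.

## Synthetic data generator

`generate_dataset` draws `x_ij = s_i * exp(mu_j + delta_j*[i in group 2] +
eps_ij)`: per-feature baselines mu_j ~ U(2, 5) (abundances roughly 7-150 in
arbitrary units), noise eps ~ N(0, log_sd^2) with log_sd = 0.5,
size effects s_i log-uniform on (0.2, 5) — a strong, urine-dilution-scale
effect — and delta_j = 1.5 (natural log) on a seeded random subset of
n_biomarkers = 5 of d = 100 features, with groups of 10 + 10. Log-normal
noise is homoscedastic on the log scale and therefore multiplicative —
heteroscedastic — on the raw scale, matching the variance-grows-with-mean
behaviour of real intensities. Contamination follows `x~ = x*M + A` with
M from U(0.2, 0.5) or U(2, 10) (fair coin) and A ~ U(2, 5), applied to a
fraction of cells drawn once per run from U(0.05, 0.15) by default (fixed
levels for the power studies); positivity is preserved. The abundance range
was chosen so the additive term A matters for low-abundance features rather
than vanishing, as it would at realistic raw LC-MS intensities of 1e4-1e7.

What the generator does *not* emulate: feature-feature correlation,
feature-dependent noise levels, missing values/limits of detection, batch
or drift structure, and realistic departure of real biomarkers from a pure
log shift. Passing tests on this generator therefore show that the
machinery behaves as designed under its own model assumptions — size-effect
cancellation, robustness to the stated contamination, calibrated
permutation p-values — not that any particular performance level carries
over to a given real instrument's data.

In the cell-detection experiments the generator plants no biomarkers, so
the contamination mask is exactly the ground truth; in the biomarker
experiments 5 biomarkers are planted and contaminated cells may coincide
with biomarker cells (an exclusion flag is not applied — the overlap is
part of the difficulty).

## Numerical choices

* MAD constant fixed at 1.483; even-length medians are midpoints;
  antisymmetry of the fitted centers is exact by the mirror construction.
* Strict inequality |u| < c in the biweight indicator, so the adjusted
  Tukey equals exactly +-1 at |u| = c.
* Ties in ranking break by feature order (stable sort); ties between
  equally large candidate reference groups break by first appearance.
* Values <= 0 are a hard error by default (log ratios undefined), with an
  opt-in half-minimum column imputation, a standard metabolomics practice.
  Missing values are rejected, not imputed.
* The ROC uses all unique score thresholds with ties grouped and the
  trapezoidal area (scikit-learn's roc_curve/auc).
* All randomness (generator, contamination, permutations, tie-breaks) goes
  through numpy Generators seeded explicitly; equal seeds give identical
  results to the byte in the CSV outputs.

## Experiment sizes

The bundled evaluation (`scripts/acceptance.py`, mirrored by the end-to-end
tests) uses 20 simulation replicates per condition at 20 x 100, B = 1000
permutation replicates (500 under the null with d = 50), and one 44 x 2336
table to exercise the streaming path — sizes at which the whole suite runs
in well under five minutes on a single core while the Monte-Carlo summaries
(mean AUC, mean rank, TPR/TNR, rejection rates) are stable to within a few
hundredths across seeds.

## Known limitations

* **Hampel's zero plateau hides moderate contamination.** With log-scale
  noise 0.5, a pairwise log ratio has scale ~0.71, so a multiplicative
  down-effect M in (0.31, 0.5) lands inside Hampel's plateau |u| < c1 and
  scores exactly 0, and even the strongest down-effect (M = 0.2) reaches
  only |u| ~ 2.28 < c3 = 2.33, never saturating. Under these conditions
  about 60% of contaminated cells tie at 0 with the bulk of clean cells and
  the Hampel AUC stays near 0.70 while Tukey — which has no plateau and so
  preserves ranking information — reaches ~0.82. At lower noise (log_sd
  around 0.25) the ordering reverses and Hampel's sharp saturation wins.
  Consequence: for *ranking/ROC* use the adjusted Tukey function; Hampel is
  the choice for visually clean heatmaps where small deviations should
  display as white.
* The method is supervised (the reference group enters standardization)
  and judges outlyingness *relative to that group*; with very small or
  contaminated reference groups the centers/scales themselves degrade.
* Biomarker identification is limited to exactly two groups.
* No outlier cutoff on W is provided by design; downstream interpretation
  is visual or via the permutation test.
* The permutation scheme treats features within a sample's row as
  exchangeable under the null; strong feature-feature correlation would
  distort its calibration.
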