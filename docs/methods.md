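# Methods

This note documents the statistical design of `radscore`: the model and
procedure each stage implements, the parameters that matter and their
defaults, what the synthetic data emulate (and do not), numerical
choices, and known limitations.

## Study design being modeled

Each observation is one adrenal gland that looks normal on
cross-sectional CT in a primary-aldosteronism patient. The label comes
from adrenal venous sampling: 1 when that gland is nonetheless the
dominant aldosterone-secreting side, 0 when it is the non-dominant side.
The derivation cohort holds 120 adrenals (60/60 by label) and a
temporally later validation cohort holds 50 (25/25). Inputs are a
107-feature radiomic table per cohort (seven standard classes:
14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
5 NGTDM), optional second-rater replicate tables, and a 24-variable
clinical table per patient.

## Reproducibility (ICC) filter

Two independent delineations of the same gland yield two feature values;
features that disagree across raters are dropped before any modeling.
We use ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

with `n` subjects and `k = 2` raters. The retention threshold defaults
to 0.75, the usual radiomics reproducibility convention; both the
threshold and the filter itself are configurable. A significance-test
variant was considered and not implemented: a fixed threshold is the
dominant practice and is directly interpretable.

## Iterative stability selection

The selection loop treats feature choice as a stability problem: a
feature is trusted only if it keeps being selected by sparse models
across many random train/test splits at many split ratios.

Per candidate (one iteration × one ratio):

1. **Stratified split** at the ratio's train fraction. Per label stratum
   the train share is `round(f · n_stratum)`, so the balanced cohort
   yields 96/24 at 8:2 and 78/42 at 6.5:3.5. Stratification is a design
   choice: it keeps every split's class balance equal to the cohort's,
   which the evaluation metrics (balanced-class kappa identity) assume.
2. **Standardization** with training means and sample standard
   deviations (n−1 denominator); test parts always reuse the training
   parameters. Exact zero-variance features are removed first (they
   cannot be standardized and carry no information).
3. **Redundancy filter**: for each feature pair, Pearson correlation if
   both features pass Shapiro–Wilk normality at α = 0.05, Spearman
   otherwise; a pair with |r| > 0.9 and correlation-test p < 0.05 loses
   one member. Scanning is greedy in column order. Within a pair the
   member with the smaller permutation-screen p survives (computed on
   demand with a capped permutation count), remaining ties break
   lexicographically. The surviving set depends on scan order; the order
   is fixed and documented for exact reproducibility.
4. **Permutation screen**: per-feature two-sample Monte-Carlo
   permutation test on |mean₁ − mean₀| with add-one correction
   `p = (1 + #extreme) / (B + 1)`, default B = 9999; features with
   p ≥ 0.05 are removed. All features share one set of label
   permutations, making the screen a single matrix product.
5. **Lasso**: penalized regression of the binary label on the surviving
   standardized features. The penalty grid is logarithmic over four
   decades down from the smallest penalty that nulls all coefficients
   (100 points); 10-fold CV picks the penalty with minimum mean squared
   error (deliberately *not* a one-standard-error rule). The CV path is
   computed per fold with warm-started coordinate descent on
   fold-centred arrays, which avoids per-grid-point input validation and
   keeps 7000 candidates at roughly three minutes on one CPU.
6. **Acceptance gate**: the candidate's RS is computed on both parts;
   it is accepted iff the unpaired DeLong test finds no train/test ROC
   difference (p > `delong_alpha`) *and* the test-set RS separates the
   label groups (permutation p < 0.05). The DeLong gate default is 0.05;
   a stricter 0.50 variant is exposed as configuration since both
   appear as reasonable gates (a larger value demands closer train/test
   agreement).

Accepted candidates increment a count for each nonzero-coefficient
feature. Features counted strictly more than `min_count` (default 100,
against 7000 candidates) form the robust set. Counting is
per-accepted-model: a feature can earn up to seven counts per iteration,
one per ratio.

Every candidate runs on an RNG substream derived from
`(master_seed, iteration, ratio_index)`, so any single candidate is
reproducible in isolation and the whole loop is bit-identical across
reruns.

## Final models and the Radiomics Score

On the robust features the derivation cohort is re-split 65/35 and six
families are trained:

- **ridge / lasso** — penalty by 10-fold CV at minimum MSE (lasso shares
  the selection loop's code path; ridge searches `10^-3..10^3`);
- **logistic regression / LDA** — unpenalized at default settings; the
  LDA scorer is the posterior log-odds direction so the same
  Youden/permutation machinery applies;
- **KNN** — k over 1..50 by 10-fold CV accuracy, ties toward smaller k,
  Euclidean distance on standardized features, probabilities are
  neighbour vote fractions; grid points exceeding the fold training
  size are skipped with a log message;
- **SVM** — a disjoint 65/17.5/17.5 train/validation/test split
  (proportions configurable; the three-way split sizes are a
  documented default, not a reported value). One SVC per implementable
  kernel (linear, RBF, polynomial, sigmoid, Laplacian via a kernel
  callable with a median-heuristic bandwidth; cost fixed at 1), the
  kernel with the best validation accuracy wins, and probabilities come
  from a logistic (Platt) calibration of decision values fit on the
  validation part. Bessel and ANOVA kernels have no counterpart in the
  underlying library and are logged and skipped, never substituted.

Each family is assessed identically: Youden cutoff fixed on the training
part (ties broken toward higher specificity, the lower-misdiagnosis
direction) and reapplied unchanged to the test part; AUC with DeLong
variance and normal-approximation CI; sensitivity/specificity/accuracy/
error rate/recall/F1/kappa/PPV/NPV from the confusion matrix at that
cutoff; an unpaired DeLong gate between the two ROC curves; permutation
tests of the score between label groups on both parts. A family
*succeeds* when both permutation tests reject at 0.05. Among successes
the best scorer has the top test AUC, ties broken by the smaller
train−test AUC gap, then the higher train AUC.

## Clinical integration

Clinical covariates are imputed (mean if Shapiro–Wilk accepts normality
at α = 0.05, median otherwise, mode for categorical; observed cells are
never altered), then screened: chi-square for categorical (Fisher's
exact for 2×2 tables with an expected cell under 5), t-test for
continuous variables normal in both groups, Mann–Whitney otherwise;
flagged at p < 0.05.

Flagged covariates plus RS enter staged logistic selection: a
univariate round drops candidates with p ≥ 0.05, then multivariate
rounds iterate (fit, drop all non-significant terms, refit) until every
remaining term is significant or nothing remains. P-values are
**likelihood-ratio tests** of each term (full model vs the model
without it). The usual Wald statistics collapse here: when the RS is
strong the joint logistic fit is quasi-separated and Wald standard
errors inflate (the Hauck–Donner effect), silently discarding genuinely
informative covariates; the LR test keeps ranking terms sensibly in
that regime. Maximum likelihood is used whenever it is stable; under
separation a weak-ridge (1e-4) IRLS fit stands in with a logged
warning, and the unpenalized likelihood is evaluated at the penalized
estimate.

The retained terms (RS always among the candidates; the pipeline forces
it into the final model if the staged procedure drops it, with a
warning) are fit by one logistic model whose fitted probability is the
Clinical–Radiomic Score. Its Youden cutoff is computed on derivation
data; an adjusted operating cutoff (e.g. one trading sensitivity for
specificity) can be supplied and is honored in all reports.

The nomogram linearizes this model: per-variable points
`100 · β_v (x − ref_v) / S` with `S = max_w |β_w| · range_w`, where
`ref_v` sits at the end of the variable's derivation range with the
lowest risk contribution (minimum for positive coefficients, maximum
for negative ones). This keeps every axis non-negative, lets the
largest-swing variable span 0–100, and makes the total-points →
probability mapping an exact inversion of the logistic link (verified
to 1e-6 in tests).

## Evaluation primitives

All inference is implemented from first principles and checked against
independent oracles in the test suite:

- **AUC** via the Mann–Whitney kernel (ties ½), variance via DeLong
  structural components; equals exhaustive pair counting on every small
  instance.
- **DeLong comparison**: paired variant (component covariances) for two
  scores on the same samples; unpaired variant (variance sum) for
  disjoint cohorts such as the train-vs-test gate.
- **Permutation test**: |mean difference| statistic, Monte-Carlo with
  add-one correction; matches exhaustive enumeration at 3-vs-3.
- **Youden cutoff**: exhaustive over midpoints of adjacent sorted unique
  scores, ties toward specificity.
- **Hosmer–Lemeshow**: equal-frequency deciles (ties kept together,
  degenerate groups merged), statistic Σ (O−E)²/(E(1−E/n_g)),
  df = groups − 2.
- **Calibration bins**: equal-frequency; **decision curves**:
  NB(t) = TP/n − FP/n · t/(1−t) on a 0.01–0.99 grid with treat-all and
  treat-none references.
- Rates with empty denominators are reported as undefined (NaN), never
  as 0.

## Synthetic data: what it emulates and what it does not

The generator plants exactly the structure the pipeline's stages are
designed to detect, with ground truth returned alongside every table:

- 107 features in the standard seven-class breakdown
  (14/18/24/16/16/14/5). Latent draws are standard normal; GLSZM, GLDM
  and NGTDM columns pass through `exp(x/2)` so the normality-adaptive
  branches (Pearson/Spearman, mean/median imputation) are exercised.
- Five informative features with a standardized location shift of
  d = 1.2, drawn as an equicorrelated block (ρ = 0.5, configurable).
  The block correlation is deliberate and matters: radiomic features
  within a signal complex are strongly inter-correlated in practice,
  and an independent five-feature signal at this effect size would put
  the population RS AUC near 0.97 — an unrealistic ceiling that leaves
  clinical covariates nothing to add. With the block the RS lands
  around 0.86–0.90, the regime the clinical fusion stage is meant for.
  Single-feature discrimination is unchanged: each informative
  feature's standalone AUC is Φ(d/√2) regardless of ρ.
- Five redundant pairs at latent correlation 0.95, both members drawn
  from the same transform group so the planted |r| ≥ 0.9 survives the
  monotone per-class transforms; two exactly constant columns.
- Rater replicates: truth plus independent Gaussian noise per rater, so
  a feature with between-subject variance σ²_b and noise variance σ²_e
  has expected ICC σ²_b/(σ²_b+σ²_e).
- Clinical tables: all 24 covariates with invented but plausible
  marginals (normal anthropometrics, log-normal aldosterone/renin/
  triglycerides/urinary measures, binary gender). Group differences are
  planted only in the seven variables the screening stage should flag
  (potassium, septal thickness, uric acid, urinary aldosterone
  excretion, renin, maximum aldosterone, triglycerides), signed so the
  control side carries higher aldosterone indices and lower potassium,
  renin, triglycerides and uric acid; d = 0.8 on the latent scale.
- Phantoms: ellipsoid masks (analytic volume known) around a smoothed
  random texture with a superior–inferior intensity gradient; voxel
  spacing recorded in the NIfTI header.

What it does **not** emulate: CT physics and scanner protocol effects,
real inter-feature correlation spectra beyond the planted blocks,
anatomically shaped ROIs, inter-rater bias (only variance),
missing-not-at-random patterns, or any coupling between radiomic and
clinical signal (they are independent by construction). Passing tests
therefore demonstrate that the *procedures* behave as specified under
controlled structure — not that the pipeline attains any particular
performance on real adrenal CT.

## Extraction front-end

The front-end contract is `engine(image, mask, spacing, config) →
{feature_name: value}`; any radiomics engine can be adapted to it, and
tests also run a deterministic mock. The built-in engine computes the
full 107-name inventory directly: mask-geometry shape descriptors
(PCA axis lengths, face-count surface area, sphericity, per-plane
maximum diameters), first-order statistics of the masked intensities,
and gray-level co-occurrence, run-length, size-zone, dependence and
tone-difference statistics on a fixed-bin-width discretisation (default
width 25). Texture matrices use the three axis-aligned offsets
(averaged) rather than all 13 3D directions, and maximum 2D/3D
diameters are computed over axis-extreme candidate points — compact
deterministic choices adequate for a front-end whose contract is the
named, class-tagged feature row, not numerical parity with any
particular engine.

## Problem sizes in the tests

The test and acceptance suites scale the loop rather than gate it: the
procedural candidate count runs the full 1000 × 7 schedule on a
20-feature table with B = 99 screen permutations; recovery runs 200 × 7
on the full 107-feature table with B = 199; the end-to-end pipeline
checks run 50 × 7 with proportionally scaled count thresholds. These
sizes are the package's chosen desk-scale defaults; the full-scale
configuration (1000 iterations, B = 9999, min_count 100) is the library
default and runs unchanged, just longer.

## Known limitations

- The iterate-until-stable multivariate pruning drops *all*
  non-significant terms per round; with mutually correlated candidates
  this can discard a genuinely informative covariate that single-step
  backward elimination would keep. Both behaviors were examined; the
  all-at-once rule is kept as the procedure's defined form.
- At cohort scale (n = 120) the conditional power to retain a d = 0.8
  clinical covariate given a strong RS is moderate; occasional spurious
  retentions and missed true covariates are expected and visible in the
  seeded examples.
- Hosmer–Lemeshow p-values on the 50-sample validation cohort are
  unstable (few events per decile); they are reported but should be
  read with that caveat.
- The built-in extraction engine is not a drop-in numerical replacement
  for established engines; only the contract (names, classes, counts,
  determinism, geometry sensitivity) is guaranteed.
- The full-scale configuration's runtime is dominated by the screen's
  permutation count; B is configurable and the add-one-corrected
  p-value floor 1/(B+1) should be kept well below the screen α.
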