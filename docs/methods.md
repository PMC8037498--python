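# Methods

`mirpanel` implements a circulating-miRNA biomarker discovery workflow for
a rare-disease case/control design (MNGIE vs. healthy): quality control and
normalization of RT-qPCR panels and small-RNA sequencing counts,
differential expression on both platforms, signature refinement, a
cross-platform meta-analysis that yields a small biomarker panel, ROC
evaluation of that panel, longitudinal tracking under therapy, and
target/enrichment annotation. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Measurement model

qPCR reports a quantification cycle Cq per (miRNA, sample); abundance is
proportional to 2^-Cq, so *lower* Cq means *more* template. All normalized
quantities flip this orientation: normalized Cq = (reference level of the
sample) − (assay Cq), so *higher* normalized values mean *more abundant*,
and group differences of normalized values are directly log2 fold changes.

Sequencing reports integer read counts per miRNA with a per-sample total of
mapped reads. Abundance is expressed as TPM (reads per million mapped:
`count / mapped_total * 1e6`); between-sample composition bias is corrected
with TMM scaling factors.

## Quality control

* **Hemolysis.** dCq = Cq(miR-23a) − Cq(miR-451). miR-451 is an
  erythrocyte miRNA, miR-23a is stable in plasma/serum, so lysis lowers
  Cq(miR-451) and raises dCq. Two published cut-offs exist (no hemolysis at
  ≤ 5; clear hemolysis above 7); they are reconciled as a *warn* band
  (5, 7] and exclusion strictly above 7, both configurable. Samples with an
  undetected marker are flagged indeterminate, never auto-excluded.
* **Detection limit.** Cq above 37 cycles is treated as undetected.
  Undetected cells stay missing downstream; they are *not* imputed to the
  ceiling, because imputing 37 would bias ddCq toward zero for
  low-abundance assays.
* **Negative controls.** An assay is flagged for exclusion unless every
  detected Cq sits at least 5 cycles below its no-template control; a
  silent control falls back to Cq 37.
* **Spike-ins** (UniSp2/4/6/3 monitoring extraction, RT and PCR) yield
  advisory flags when a sample deviates from the channel median by more
  than 2 cycles; they never exclude samples on their own.

## Normalization

* **Global mean** (discovery-style): the reference set is the assays
  detected in *all* samples; normalized Cq = per-sample mean Cq of that set
  minus the assay Cq. The normalized mean over the reference set is 0 in
  every sample, and adding a constant to one sample's Cq values (an RNA
  input shift) cancels exactly.
* **Reference-gene stability** is a model-based variance decomposition on
  the log scale. Working directly with −Cq·ln 2 is mathematically identical
  to log-transforming 2^-Cq values and avoids underflow. Within each group
  g, after removing per-sample means (the RNA-amount effect), gene i has
  group mean z_ig and residual variance s²_ig; because per-sample means are
  estimated over I genes, E[s²_ig] = σ²_ig(1 − 2/I) + σ̄²_g/I, which the
  estimator inverts (negative estimates truncated at 0). Intergroup
  deviations d_ig = z_ig − Σ_h w_h z_ih are shrunk toward zero with an
  empirical-Bayes factor γ²/(γ² + σ²_ig/n_g), where γ² is the between-gene
  variance of the true deviations (method-of-moments, truncated at 0). The
  stability value is the mean over groups of |shrunken deviation| +
  √(sampling variance + posterior variance); lower = more stable. A
  candidate *pair* is scored by treating the average of the two
  sample-centered profiles as a pseudo-gene (residual variance
  (σ²_a + σ²_b)/4 under independence), so a pair of anti-correlated or
  merely independent stable genes beats either single.
* **TMM factors** follow the trimmed-mean-of-M-values recipe: reference
  sample = the one whose upper-quartile count fraction is closest to the
  mean fraction; per sample, M and A values over doubly positive genes,
  30% trims on M and 5% on A from each tail, delta-method precision
  weights, factors rescaled to geometric mean 1. Note that the precision
  weights depend on absolute counts, so scaling one library rescales the
  relative weights slightly; the factors are scale-*stable* (log2 shift
  well under 0.05) but not exactly scale-invariant — a property of the
  published weighting itself.
* **Exploratory transforms**: Ward clustering on Euclidean or
  1 − Pearson distances (features optionally Z-scaled first, constant
  features dropped under the correlation metric), SVD-based PCA with
  centering (unit scaling only on the Z-scale path), and a top-variance
  feature pre-filter.

## Differential expression

* **qPCR (ddCq)**: per feature, ddCq = disease mean − healthy mean of
  normalized Cq; log2 FC = ddCq under the higher-is-more-abundant
  orientation, so upregulated ⇒ FC > 1. (The printed relative-quantification
  formula FC = 2^−ΔΔCq and the normalization orientation are inconsistent
  as published; the implementation follows the stated interpretation
  "values > 1 are upregulation", which also matches the printed fold-change
  directions.) Signed display convention: FC < 1 is reported as −1/FC.
  Two-sided pooled-variance t-test; features with fewer than two detected
  values in a group are skipped and excluded from the BH family.
* **Counts (NB)**: an exact-style small-sample negative-binomial test.
  Counts are scaled to a common effective library (mapped total × TMM
  factor, geometric-mean target). Dispersion is a 50/50 blend of the
  per-feature method-of-moments estimate and a common profile-likelihood
  estimate (floor 1e-6). Under a shared dispersion and equalized libraries
  the two group sums are NB with a common success probability, so the
  group-A sum conditioned on the total follows a negative-binomial analogue
  of the hypergeometric; the two-sided p-value sums all outcomes no more
  probable than the one observed. For conditional totals above 20,000 the
  conditional law is replaced by its normal approximation (variance
  V_A V_B/(V_A+V_B)); at that depth the discrete and continuous tails
  agree to well below the test's granularity. Log2 FC uses group means of
  equalized counts with a 0.5 prior per group to keep zero rows finite.
  Type-I calibration (simulated nulls at μ=100, dispersion 0.1, n=8/group)
  sits inside [0.03, 0.08] at nominal 0.05, which is the accuracy claim
  this test makes — it does not promise bit-identity with any particular
  published implementation.
* **BH adjustment** is the step-up rule with cumulative-minimum
  enforcement; the family is the set of actually tested features.
* **Stratified union**: features significant in any age-stratum comparison
  are counted once; conflicting directions across strata are flagged.

## Signature refinement

Multinomial elastic net on standardized predictors, outcome = group ×
age-stratum classes (a pooled-healthy 4-level coding is also available;
the published description is ambiguous between the two). The mixing
parameter defaults to 0.5 — the source names only "elastic net", which
implies a ridge component — and the penalty path is 25 (12 in the fast
paths) log-spaced values from the data-derived λ_max down to λ_max/1000.
λ is chosen at the 10-fold CV minimum of multinomial deviance (the
conventional default report; not the 1-SE rule). Fold assignment is
seeded, coefficients are mapped back to the original feature scale, and
the retained signature is the union of features with any non-zero class
coefficient. With strong signals the CV-minimum model is legitimately
dense — penalized multinomial fits at the deviance-minimizing λ keep many
small coefficients (the study's own refinement kept 41 of 80 predictors) —
so recovery guarantees are stated for *signal* features, not for a sparse
noise floor. The binary AUC of a multiclass model collapses class
probabilities to a disease score (sum of disease-class probabilities); a
macro one-vs-rest AUC is reported alongside.

**Power**: the validation sample size is the smallest n per group for
which a two-sided two-sample t-test at level α reaches the target power,
computed from the noncentral-t distribution with a normal-approximation
initializer (d = 1.0, α = 0.05, power = 0.80 gives n = 17 per group; the
published power statement omits its effect size, so d is an explicit
input, and 17/group is treated as a consistency anchor).

## Meta-analysis, panel and ROC

Per-feature raw two-group p-values from the two platforms (sequencing
serum, qPCR plasma or serum) are combined with Fisher's method
(−2Σln p ~ χ² with 2k df; a single input is returned unchanged; zeros are
clamped to 1e-300). Raw rather than adjusted p-values enter the
combination because adjusted values are not exchangeable across different
family sizes; the named combination function's rule is not printed, so
Fisher is the default with Stouffer available. The panel is every feature
with combined p below 1e-4, in rank order.

Each panel member is evaluated by univariate binary logistic regression
(IRLS maximum likelihood; on separation or collinearity a
ridge-stabilized fit is used and flagged non-converged) with the AUC
computed as the mid-rank Mann–Whitney statistic on the fitted disease
probability, a DeLong asymptotic 95% CI, and a DeLong z-test against AUC
0.5. The combined panel uses the multivariate logistic fit the same way.
Perfect separation yields AUC 1 with a degenerate CI.

**Longitudinal performance**: fold change of each panel feature versus the
same patient's pre-therapy baseline, 2^(norm_t − norm_0) on the
reference-pair-normalized scale; patients without a baseline are skipped
with a reason.

## Targets, network, enrichment

Predictions from four offline sources (live database queries are out of
scope; source exports are supplied as TSV tables) are aggregated per
(miRNA, gene): a pair needs support from ≥ 2 sources; each source's scores
are first mapped to (0, 1] by within-miRNA rank/n (making the aggregate
invariant to any monotone rescaling of incommensurable source scores), and
the aggregate is the geometric mean over supporting sources. The panel's
consensus targets form a bipartite miRNA→gene network keeping genes
targeted by ≥ 2 panel miRNAs. GO-style term enrichment uses the two-sample
Kolmogorov–Smirnov test on member vs. non-member ranks of the
consensus-score-ordered gene list; the two-sided exact form is used (on
the tiny worked case — a 2-gene term holding ranks {1, 2} of 4 — it equals
the 1/3 obtained by enumerating rank assignments). Pathway enrichment is
the hypergeometric upper tail with BH adjustment. Both null distributions
are discrete, hence super-uniform rather than exactly uniform: rejection
rates at nominal α stay at or below α (verified by permutation), which is
the correct conservative behavior for these tests.

## Synthetic studies

The generators produce data with the statistical structure the analysis
assumes, with the planted truth returned alongside:

* **qPCR**: baseline Cq ~ U(22, 34) per feature, Gaussian technical noise
  of 0.8 cycles (chosen so a 10-per-group study has high power for
  |log2 FC| ≥ 1.1, matching the scale of the published discovery-phase
  effects, which the default effect profile copies: 2.1- to 7.1-fold up,
  2.1- to 6.1-fold down across 27 features), four designed normalizer
  features with zero effect and a quarter of the noise, the hemolysis
  marker pair at fixed baselines, spike channels at constant Cq + 0.15
  cycles of noise, and detection cut at Cq 37. Hemolysis injection lowers
  the erythrocyte miRNAs (miR-451a, miR-16-5p, miR-486-5p — the set that
  co-varies under lysis) to reach a chosen dCq.
* **Counts**: log-normal abundance proportions, log-normal library sizes
  around 1.5 million mapped reads (the published per-sample average),
  gamma-Poisson counts at dispersion 0.15, group effects as multiplicative
  2^log2FC on disease samples, optionally per age stratum with the
  published per-stratum effect scale as default.
* **Treatment**: panel features decline by a fixed log2 step per
  timepoint with a configurable relapse reversal; two constant reference
  assays ship with the matrix for normalization.
* **Annotation fixtures**: four prediction sources with controlled
  consensus composition (default geometry: 52 genes hit by two panel
  miRNAs and 2 by three), plus term/pathway tables with plantable
  enrichment.

What the generators do *not* emulate: amplification-efficiency
differences and melting-curve artifacts (accepted as upstream metadata),
miRNA-correlated technical batch structure, UMI/read-level noise,
zero-inflation beyond NB sampling, and real inter-patient heterogeneity of
effect sizes. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated sampling models, not clinical performance
on real cohorts.

## Problem sizes and numerics

Default test/demonstration sizes are chosen to exercise every code path at
desk scale: 17 per group × 100 features for the qPCR arm (the power
calculation's n), 5 per group per stratum for the sequencing arm, 2,000
features for null calibration, 500 simulations for CI coverage, 50–200
seeds for recovery rates. Tolerances: stability oracle agreement 1e-8; TMM
oracle agreement 1e-6; BH/hypergeometric/Fisher agreement ~1e-10;
variance floors 1e-6 (dispersion) and 1e-300 (p-value clamp). Ties are
broken deterministically (mid-rank AUC ties, feature-id order for equal
combined p, "first" ranks inside TMM trimming), and every stochastic
routine takes an explicit seed.

## Known limitations

* The exact published stability values, combined p-values and AUCs are not
  reproducible without the study's raw data (not deposited); those numbers
  are covered by oracle equivalence and planted-truth recovery instead.
* The printed per-stratum differential-expression table does not include
  the overall-comparison-only hits, so its union yields 78 unique features
  against the 80 reported in the text.
* The NB test approximates the conditional law at very large totals; the
  logistic ROC p-value is asymptotic (DeLong) and anti-conservative at
  very small n; the K-S enrichment treats GO terms as flat sets (no graph
  propagation).
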