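# Methods

This note documents the statistical machinery implemented in `mbfuse`, the
defaults it ships with, and the design decisions taken where more than one
reasonable choice existed.

## Preprocessing of count tables

**Filtering.** A feature (ASV) is retained iff (a) its summed count across
the dataset is at least `min_total_fraction` (default 0.01) of the grand
total *and* (b) it is nonzero in at least `min_prevalence` (default 0.25)
of the samples.  The abundance rule is applied per dataset, not per sample:
under a per-sample reading almost no feature in a realistically deep
library survives a 1% cut, so the per-dataset reading is the only workable
one.  Both comparisons are inclusive (`>=`) at the boundary, and the filter
is idempotent.

**Cumulative sum scaling (CSS).** Each sample's scaling factor is the sum
of its counts up to its own empirical quantile `l` of *nonzero* counts;
counts are divided by the factor and multiplied by `scale` (default 1000).
Zeros are excluded from the quantile, matching the behavior of the standard
implementation of this normalization.  The reference quantile is chosen
adaptively: scanning the grid {0.05, 0.10, …, 0.95}, the chosen level is
the smallest at which the median deviation of per-sample cumulative sums
from their across-sample median, divided by the median library size,
first exceeds 0.1.  This instability curve starts near zero and grows with
the level, so the scan stops where partial sums begin to diverge across
samples.  Two natural alternatives — relative deviation of raw cumulative
sums, or of within-sample fractions — are degenerate in opposite
directions (the first trips at the lowest grid level whenever library
sizes vary at all; the second is a decreasing curve), which is why the
depth-scaled absolute form is used.  If the criterion never triggers (e.g.
identical samples) the conventional 0.5 is returned with a warning.

**Scales used downstream.** Alpha diversity is computed on *raw* counts:
Chao1 needs integer singleton/doubleton counts, and CSS rescaling would
corrupt them.  Beta diversity, ordination and the chemometric engine use
CSS-normalized values; taxa enter PLS-DA as `log1p(CSS)`, the variance-
stabilized scale on which linear latent-variable models are appropriate
for compositional count data.  Univariate taxa tests run on relative
abundances; metabolite tests run on the quantified concentrations.

## Ecology

- Shannon entropy defaults to **base 2** (bits), with the base exposed;
  Simpson is the Gini–Simpson form `1 − Σ p_i²`; Chao1 is the
  bias-corrected estimator `S_obs + F1(F1−1)/(2(F2+1))`.
- Bray-Curtis dissimilarity `1 − 2Σmin(x_i,x_j)/(Σx_i+Σx_j)` is the
  implemented beta metric.  UniFrac is deliberately out of scope: it
  requires a phylogeny this package does not construct.
- PCoA applies Gower double-centering to `−½d²` and eigendecomposes;
  negative eigenvalues (non-Euclidean inputs) are reported but their axes
  dropped, and variance proportions are taken relative to the positive
  eigenvalue total.  Axis signs are fixed by forcing the largest-magnitude
  coordinate positive, so reruns are byte-identical.
- PERMANOVA computes the pseudo-F from within/total sums of squared
  distances.  When the number of distinct label assignments is at most
  `n_perm`, the exact permutation distribution is enumerated and p is the
  exact tail fraction (identity included); otherwise p uses the add-one
  estimator `(1 + #{F* ≥ F})/(1 + n_perm)`, which cannot return 0.

## Univariate testing

Two multiplicity regimes are used for the two roles univariate tests play:
Kruskal-Wallis + Benjamini-Hochberg FDR for table-wide scans (features are
flagged when raw p ≤ 0.05 *and* FDR-adjusted p ≤ 0.1, the conjunction
rule), and Mann-Whitney + Bonferroni (α = 0.05) for confirming the few
VIP-selected features.  Mann-Whitney switches to the exact null
distribution when the combined sample size is ≤ 12 and the data are
tie-free, otherwise the tie-corrected normal approximation is used.  A
Kruskal-Wallis input in which every observation is identical returns
H = 0, p = 1 rather than an error.  Clinical correlations use
pairwise-complete deletion; rows with any missing value among the nine PCA
variables are dropped (with a logged count) before the clinical PCA —
the simplest auditable rule.

Cut-off stratification schemes are explicit objects: blood pH severity
(severe < 7.10 ≤ moderate < 7.32 ≤ normal; intervals are half-open, the
boundary belongs to the upper stratum), the binary pH split at 7.32, and
anti-GAD positivity (strictly > 1 U/mL, so exactly 1.0 is "low").

## PLS-DA, fusion, and validation

**PLS-DA.** Two-class problems are coded as a single centered 0/1 dummy
and fitted with NIPALS PLS1; with one response the weight direction is the
closed form `w_a ∝ X_a'y_a`, so each component is a single deflation step.
`scale=False` still mean-centers — centering is intrinsic to PLS.  Fitted
predictions at the full rank of X coincide with ordinary least squares,
which the tests use as an oracle.  The class rule is positive iff the
predicted dummy ≥ 0.5 (a tie at the threshold goes to the positive class);
the threshold is stored on the model.  Zero-variance columns (globally or
inside a CV fold) are neutralized — centered to zero with a unit scale —
rather than physically dropped: this is algebraically equivalent for any
linear model and keeps column indices stable for VIP bookkeeping.

**VIP.** `VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_a't_a`; the identity `Σ_j VIP_j² = p` holds for every fit
and is asserted property-style in the tests.

**Low-level fusion.** Each block is autoscaled within-block, divided by
its Frobenius norm, and concatenated row-wise.  Scaling any raw block by a
positive constant leaves the fused matrix exactly unchanged.  Inside
cross-validation the order is: autoscale each block on the training
partition → divide by the *training-partition* Frobenius norm →
concatenate; held-out rows are transformed with the training parameters
only.

**Repeated double cross-validation.** Defaults: 5 outer × 5 inner
stratified folds, 20 repetitions, up to 10 latent variables.  Folds are
stratified by class with cyclic dealing after a seeded shuffle; a class
smaller than the outer fold count is an error.  The inner criterion is
mean classification error over the inner folds, evaluated for all
component counts from a single nested NIPALS fit; ties go to the smaller
model.  Per repetition, the pooled out-of-fold predictions give one
accuracy/sensitivity/specificity triple; results are reported as
mean ± SD over repetitions.  VIPs are taken from one refit per repetition
on all samples at the median chosen component count (lower median when
even) — a declared choice; per-fold VIPs would be equally defensible but
mix models of different complexity.  A master seed spawns independent
per-repetition substreams, so results are exactly reproducible and
repetitions are independent.

**Permutation test.** Class labels are permuted `n_perm` times and the
figure-of-merit computation is repeated at a reduced number of repetitions
(default 1) per permutation.  Observed and permuted statistics go through
*identical* machinery — the same fold plans (stratified by the observed
labels) and the same fold-local preprocessing, computed once and reused.
This is the condition for exactness under label exchangeability: an
earlier variant that compared a stratified-for-truth observed statistic
against unstratified permuted replicates was measurably anti-conservative
(empirical type-I ≈ 0.085 at α = 0.05; nominal after the change).
Preprocessing reuse is valid because fold-wise autoscaling and Frobenius
norms depend only on X and the fold structure, never on the labels.
p-values use the add-one estimator, bounded below by `1/(n_perm+1)`.

**Leakage discipline.** No test-fold row influences preprocessing,
component selection, or model fit.  The suite audits this with a
construction in which a column encodes the class label only on the rows
of one outer test fold: the models predicting those rows never saw the
column as informative, so accuracy must stay at chance — and does.

## The synthetic-data generator

The generator emulates the design of a three-group pediatric T1D-onset
study so every downstream stage is testable with known ground truth.

- **Design**: groups T1D/sibling/CTRL of 52/17/57 samples by default.
- **Counts**: library sizes are log-normal with mean 75,154 reads and CV
  0.3 (the log-normal is parameterized so its *mean* equals the target);
  compositions are Dirichlet-multinomial with concentration 200 around a
  group-specific composition — a rank-abundance baseline (a sorted
  Dirichlet(1) draw, so low feature indices are the abundant taxa) with
  planted log2 fold changes applied and renormalized.  The
  Dirichlet-multinomial, not a plain multinomial, supplies the
  overdispersion real 16S tables show; concentration 200 gives a
  per-taxon CV of roughly 0.7–0.9 at 1% abundance, enough that a two-fold
  change at n = 60/group is detectable but not trivial.
- **Metabolites**: 37 named metabolites with log-normal marginals
  (log-scale SD 0.5); group effects are standardized mean shifts on the
  log scale.  A planted taxon–metabolite correlation `r` is realized by
  blending the taxon's standardized `log1p(CSS)` abundance `z` with
  independent noise, `e = r·z + sqrt(1−r²)·ε` — the analysis scale, so the
  planted `r` is recovered by the same transform the pipeline applies.
  `r = 0` reduces exactly to the unlinked generator.
- **Clinical**: nine variables via a Gaussian copula.  Marginal means/SDs
  follow typical T1D-onset cohort values; anti-GAD and IA-2 are
  log-normal (strongly right-skewed titers), blood pH is a two-component
  normal mixture (7.38 ± 0.04 and 7.18 ± 0.08, weights 0.46/0.54)
  straddling the 7.32 severity cut-off, and the remaining variables are
  (clipped) normals.  Latent pairwise correlations are *calibrated by
  Gauss–Hermite quadrature* so the output Pearson correlations hit the
  targets (insulin need ↔ HbA1c +0.33, insulin need ↔ pH −0.33, anti-GAD
  ↔ HbA1c −0.36) despite the non-normal marginals; the latent matrix is
  repaired to the nearest PSD correlation matrix if calibration breaks
  definiteness.  The marginal shapes themselves are modeling choices —
  cohort tables report only means ± SD — and are exposed in
  `ClinicalSpec`.
- **Determinism**: a single seed expands through `SeedSequence.spawn`
  into independent per-table substreams, so regenerating or resizing one
  table never perturbs the others.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: sequencing error and chimeras, taxon–taxon
ecological interactions beyond the shared Dirichlet baseline,
zero-inflation beyond what the Dirichlet-multinomial induces,
sibling-pair genetic structure beyond a shared group-level effect,
longitudinal sampling, batch effects, and missing clinical values.

## Problem sizes in the test suite and acceptance script

The statistical checks run at deliberately chosen sizes: null calibration
of the rDCV classifier uses synthetic null bundles with 40 + 40 samples
and 150 features (10 repetitions for the accuracy band; 200 replicates at
99 permutations with 3×3 folds for p-value uniformity and type-I error);
signal recovery plants 10 features with a 1.5 SD shift among 200 at
60 + 60 samples; the leakage audit uses 100 + 100 samples.  The
acceptance script runs the full default study (126 samples) with 10 rDCV
repetitions per model and 99 permutations for the significance test.
These sizes make every check a fraction-of-a-minute computation while
leaving the statistical conclusions stable across seeds.

## Known limitations

- Two-class PLS-DA only (one dummy response); the multi-group comparisons
  are handled as pairwise contrasts, not multi-class coding.
- No mid-/high-level fusion variants, block-weight optimization, OPLS,
  sparse PLS, or >2 blocks with per-block component counts.
- PERMANOVA assumes exchangeability under the null; no PERMDISP companion
  test is provided, so location and dispersion effects are not separated.
- The CSS adaptive quantile is a heuristic; for tables with exotic count
  distributions the fixed-quantile override (`css_quantile`) is the safer
  choice.
- Exact Mann-Whitney is limited to combined n ≤ 12; beyond that the
  normal approximation (continuity- and tie-corrected) is used.
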