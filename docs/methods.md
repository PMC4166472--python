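# Methods

## The classification model

The classifier assigns samples to K subtypes (canonically the ten
integrative-cluster subtypes, labeled `IC1`–`IC10`) by nearest shrunken
centroids over a fixed reference panel of features. For feature j and
class k:

- class centroids `x̄_kj` and overall centroid `x̄_j` are plain means
  over non-missing cells;
- the pooled within-class dispersion is
  `s_j² = Σ_k Σ_{i∈k} (x_ij − x̄_kj)² / (n_j − K)` where `n_j` counts
  the non-missing cells of feature j;
- the fudge factor `s0` is the median of the `s_j`, guarding against
  features with near-zero dispersion dominating the discriminant;
- the class-size factor is `m_k = √(1/n_k − 1/n)`, the
  variance-consistent form for the contrast `x̄_kj − x̄_j` (the
  alternative `√(1/n_k + 1/n)` convention found in some descriptions is
  available via `m_convention="plus"`);
- the standardized offset is `d_kj = (x̄_kj − x̄_j)/(m_k (s_j + s0))`,
  soft-thresholded to `d′_kj = sign(d_kj)·max(|d_kj| − Δ, 0)`;
- prediction minimizes
  `δ_k(x) = Σ_j (x_j − x̄′_kj)²/(s_j + s0)² − 2 log π_k` over available
  features, with posteriors `∝ exp(−δ_k/2)` computed after subtracting
  the row minimum for numerical stability.

Class priors `π_k` are the empirical training frequencies (the
reference cohort is taken to represent the population); uniform priors
are a deliberate non-default because subtype prevalences differ by a
factor of ~4.

### Assumptions

The model is a diagonal (independent-feature) Gaussian classifier with
equal per-feature variance across classes. It assumes features have
been placed on a common scale — hence the mandatory z-scoring — and
that a new cohort's subtype-conditional means resemble the reference
centroids up to that scaling. It does not model feature covariance;
soft-thresholding is the only feature selection.

## Threshold selection and determinism

Δ is chosen on an evenly spaced grid of 30 values spanning
`[0, max|d_kj|]` by stratified cross-validation: 10 folds, capped at
the smallest class size, scikit-learn `StratifiedKFold` with
`shuffle=True` seeded by the user's seed. The chosen Δ* is the largest
grid value attaining the minimal total misclassification count — ties
break toward sparser models. Identical seeds therefore give
bit-identical folds, error curves, thresholds and assignments; this is
surfaced everywhere because un-seeded runs of CV-based classifiers
produce slightly different assignments run to run. Within a CV fold a
rare class may be left with a single training sample; the fold-internal
fit tolerates this (its dispersion contribution is zero) while the
user-facing fit requires ≥2 samples per class.

## Partial feature panels and missing data

A study rarely provides the full 612-gene panel. Rather than imputing,
the whole training procedure is re-run against the reference cohort
restricted to the features the study provides (`retrain_on_features`),
so the centroids, dispersions and threshold are all re-estimated for
that feature subset. Prediction refuses to run below a configurable
minimum feature fraction (default 0.5 of the model's features) and the
error suggests copy-number or combined mode instead.

Missing cells are flagged at load (never imputed): during fitting they
are excluded from means and dispersions, and features missing in >50%
of samples are dropped with a warning; during prediction a sample's
missing features are excluded from its δ sums, which are rescaled by
`p_model / p_present` so discriminants remain comparable across samples
with different coverage.

## Feature matching dialects

Expression matching is case-sensitive exact equality on probe id or
gene symbol; no alias expansion (alias tables are database-version
dependent and would make matching irreproducible). In gene mode,
multiple rows mapping to one gene are averaged per sample — the mean is
symmetric and the standard choice. Segment-to-gene summarization
defaults to the overlap-length-weighted mean of intersecting segments'
log-ratios over the gene span (1-based closed coordinates throughout);
a `midpoint` dialect (log-ratio of the segment covering the gene
midpoint) is available because the field is not unanimous on this rule.

## Normalization

Each feature is z-scored within its dataset (sample sd, `n−1`
denominator, missing cells excluded; zero-variance features below
sd 1e−12 dropped and recorded). Training and test cohorts are scaled
independently — both land on the same axis, which is what makes
cross-platform assignment work: any per-feature positive affine
distortion of a platform cancels exactly. Reference-quantile mapping
and batch correction are out of scope.

## Goodness of fit

For each class with assigned samples, the Pearson correlation between
the cohort's class-mean profile and the model's *unshrunk* class
centroid over shared features; the study statistic is the unweighted
mean over non-empty classes. The unshrunk centroid is the target
because the diagnostic asks whether the cohort reproduces the training
class profiles, not the sparsified discriminant; `use_shrunken=True` is
available. Unweighted class averaging (rather than size-weighting or
correlating concatenated profiles) was chosen so that rare subtypes
count equally — the statistic is a reproducibility check, not a
sample-level accuracy.

## Evaluation statistics

- Cohen's kappa from the contingency table:
  `κ = (p_o − p_e)/(1 − p_e)` with `p_e = Σ_c mA(c)·mB(c)`. Note the
  chance agreement for ten-class labelings is 10% only under uniform
  marginals; realistic subtype frequencies push it higher (the
  simulator's defaults give ~12%).
- One-way ANOVA adjusted R² per gene:
  `1 − (1 − R²)(n − 1)/(n − k)`, computed from sums of squares.
- Explained-variation comparison: mean over a gene list of the
  difference in adjusted R² between two labelings, with a percentile
  bootstrap CI (order statistics at ranks `⌈α/2·B⌉`, `⌈(1−α/2)·B⌉`,
  B = 1000 default). The resampling unit is the **gene**: the averaged
  quantity is a mean over genes within a study, so genes are the
  exchangeable units; samples are held fixed.
- Study pooling is the sample-size-weighted mean `Σ eᵢnᵢ / Σ nᵢ`.
- Printed event rates round half away from zero to match how such
  percentages are conventionally displayed.

## The synthetic cohort generator

The generator emulates the structure the classifier assumes: each
subtype carries a characteristic archetype of locus-level copy-number
states in {−1, 0, +1, +2} over 34 loci × 18 genes = 612 genes on a
22-pseudo-chromosome grid; states exert a cis dosage effect on
expression (1.0 expression units per state unit by default) on top of a
subtype-specific basal shift per gene (sd 0.5) and Gaussian noise
(sd 1.0). Default subtype frequencies are uneven with the rarest class
at 4.5%. Archetypes are deterministic: each non-flat class has one
focal +2 amplicon, two +1 gains and one −1 deletion at class-specific
loci; class 4 is CNA-devoid, echoing the one well-known flat subtype.
Per-sample segments encode the realized locus states exactly at
log-ratio 0.5 per state unit, so gene-level copy number recomputed from
the segments inverts to the states that generated expression — a tested
consistency invariant. Basal shifts are drawn from the config seed, not
the per-cohort sampling seed, so every cohort from one config shares
the same class model and classifiers transfer between them.

Platform perturbation retains a random feature subset (e.g.
`keep_fraction=0.946` reproduces a 579-of-612 panel), applies a
lognormal scale and normal shift per feature, and adds noise. What the
simulator does **not** emulate: probe-level microarray artifacts,
RNA-seq count distributions, correlated noise, tumor purity, or the
real marginal distributions of any particular cohort. Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
dropout/affine/noise distortions — not clinical-grade accuracy on real
tumors, which the default conditions make considerably easier (the
synthetic subtype separation is strong, so held-out accuracy near 1.0
is expected, where real cross-platform concordance is ~98%).

## Numerical choices and problem sizes

- Zero-dispersion degenerate fits floor `s0` at 1e−6 to keep δ finite.
- Exact Δ=0 returns the unshrunk centroids verbatim (no floating-point
  round trip through d_kj).
- Discriminant ties break toward the larger prior, then label order.
- Test and acceptance runs use cohorts of 240–1000 samples, panels of
  3 studies of 200–400 samples, 100-noise-cohort empirical nulls, and
  25-seed sweeps — sizes chosen so the full statistical behaviour
  (rarest class ≈ 4.5% still has ≥10 training samples per fold at
  n = 1000) is exercised while a complete run stays in minutes.
- The GOF noise-null threshold frozen in the tests (0.194) is the 99th
  percentile of the study-mean |r| over 100 seeded pure-noise cohorts
  at the default dimensions, computed once with the default reference
  model.

## Known limitations

- Gene matching has no alias/version handling; callers must harmonize
  symbols first.
- The diagonal-Gaussian assumption ignores co-expression; posteriors
  are therefore overconfident on correlated panels and should be read
  as scores, not calibrated probabilities.
- `read_classification` reconstructs discriminants from posteriors only
  up to a monotone transform (sufficient for re-use, not for comparing
  δ across files).
- The simulator's dosage model is linear in state units; saturation and
  allele-specific effects are not modeled.
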