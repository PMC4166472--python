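# intclust

Gene-expression and copy-number based classification of breast tumors
into the ten integrative-cluster (IntClust) subtypes, with the
diagnostics and comparison statistics needed to evaluate such a
classifier across heterogeneous studies.

The IntClust taxonomy groups breast tumors by their pattern of somatic
copy-number alterations (CNAs) that deregulate gene expression in
*cis*. Assigning new samples to these subtypes is hard in practice
because most public studies provide expression only, on varying
platforms, with incomplete gene panels. This package implements a
platform-flexible classifier for that setting, together with a
synthetic-cohort simulator so the whole pipeline can be validated
end-to-end without controlled-access patient data. It is aimed at
computational biologists who want to subtype expression (and optionally
copy-number) cohorts, or to study the behaviour of centroid-based
single-sample classifiers.

## Method

Classification proceeds in three steps:

1. **Feature matching** — a study's features are reconciled with the
   reference catalog by probe name, gene name (multiple probes per gene
   averaged), or, for segmented copy-number calls, by genomic position
   (overlap-length-weighted mean log-ratio over each gene span).
2. **Normalization** — every matched feature is scaled to a z-score
   within the study. Because z-scores are invariant to per-feature
   positive affine transforms, cohorts measured on different platforms
   land on the reference scale.
3. **Nearest shrunken centroids** — with class means x̄_kj, overall
   means x̄_j, pooled within-class dispersions s_j and fudge factor s0,
   the standardized offsets

       d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0)),   m_k = √(1/n_k − 1/n)

   are soft-thresholded, d′_kj = sign(d_kj)·max(|d_kj| − Δ, 0), giving
   shrunken centroids x̄′_kj = x̄_j + m_k (s_j + s0) d′_kj. A sample x
   is assigned to the class minimizing

       δ_k(x) = Σ_j (x_j − x̄′_kj)² / (s_j + s0)² − 2 log π_k

   with posteriors ∝ exp(−δ_k/2). The threshold Δ is chosen by
   stratified cross-validation (largest Δ at minimal CV error), and a
   fixed seed makes the whole procedure deterministic. Studies with
   missing genes are handled by re-estimating the centroids against the
   reference cohort restricted to the available features.

Supporting statistics: per-subtype goodness of fit (Pearson correlation
between a cohort's subtype-average profile and the reference centroid),
Cohen's kappa with chance-expected agreement for comparing labelings,
per-gene one-way ANOVA adjusted R² with percentile-bootstrap CIs for
comparing how well two labelings explain expression, and size-weighted
cross-study pooling.

## Worked example

`examples/classify_external_study.py` trains on a synthetic reference
cohort (612 genes, 10 subtypes, rarest at 4.5%) and classifies a
platform-perturbed external study that provides only ~90% of the gene
panel:

```
features matched: 551/612
shrinkage threshold chosen by CV: 2.352
truth concordance: 0.996
study goodness of fit: 0.912
  IC1: r = 0.887 over 14 samples
  IC10: r = 0.924 over 27 samples
  ...
```

551 of 612 catalog genes survive the simulated platform dropout; the
classifier re-estimates centroids on those features, recovers 99.6% of
the true subtype labels, and the per-subtype correlations (~0.87–0.95)
show the study reproduces the reference expression profiles. The other
scripts in `examples/` demonstrate the centroid mathematics on a toy
problem, copy-number and combined classification modes, labeling
comparison statistics, and writing a simulated cohort to standard
files.

A thin CLI mirrors the library: `intclust simulate | train | predict |
gof | evaluate` (see `intclust --help`).

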