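"""Generate a synthetic cohort and write its standard tabular files.

Produces an expression matrix (features x samples TSV), SEG-like
segmented copy-number calls, the feature catalog with genomic
coordinates, and the true subtype labels -- the same four inputs a real
study would provide, so any downstream tooling can be exercised on
them.
"""

from pathlib import Path

import intclust as ic

outdir = Path("scratch") if Path("scratch").exists() else Path(".")
config = ic.CohortConfig(n_samples=300, seed=0)
cohort = ic.make_reference_cohort(config)

ic.write_expression_matrix(cohort.expression, outdir / "cohort.expression.tsv")
ic.write_segments(cohort.segments, outdir / "cohort.segments.tsv")
ic.write_feature_catalog(cohort.catalog, outdir / "cohort.catalog.tsv")
cohort.true_labels.rename_axis("sample_id").to_csv(
    outdir / "cohort.labels.tsv", sep="\t")

freqs = cohort.true_labels.value_counts(normalize=True)
print(f"wrote 4 files to {outdir}/ for {cohort.expression.n_samples} samples, "
      f"{cohort.expression.n_features} genes")
print(f"subtype frequencies: rarest {freqs.idxmin()} at {100 * freqs.min():.1f}%, "
      f"commonest {freqs.idxmax()} at {100 * freqs.max():.1f}%")
print(f"segments per sample: {len(cohort.segments) // cohort.expression.n_samples}")
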