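"""Core data containers and tabular IO.

The classifier touches four kinds of tabular data: feature catalogs
(the reference panel of classifier genes/probes with hg19-style
coordinates), expression / gene-level copy-number matrices
(features x samples), segmented copy-number calls (SEG-like), and
per-sample classification results.  All are thin wrappers around
pandas objects with the invariants the pipeline relies on validated
at construction and load time.

Coordinates are 1-based fully-closed intervals throughout.  Missing
matrix cells are represented as NaN and flagged, never imputed at
load time; downstream operations decide how to handle them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPRESSION = "expression"
COPY_NUMBER = "copy_number"

#: canonical 10-class label set of the integrative-cluster taxonomy
DEFAULT_CLASS_LABELS = tuple(f"IC{i}" for i in range(1, 11))

CATALOG_COLUMNS = ["feature_id", "gene_symbol", "chromosome", "start", "end", "data_type"]
SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "log_ratio"]


class DataValidationError(ValueError):
    """An input violates a container invariant."""


@dataclass(frozen=True)
class FeatureCatalog:
    """Reference panel of classifier features with genomic coordinates.

    ``entries`` has columns feature_id, gene_symbol, chromosome, start,
    end, data_type (one of ``expression`` / ``copy_number``).  Feature ids
    are unique; gene symbols may recur (several probes per gene).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"catalog missing columns: {missing}")
        dup = df["feature_id"][df["feature_id"].duplicated()]
        if len(dup):
            raise DataValidationError(f"duplicate feature id {dup.iloc[0]}")
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "feature_id"].iloc[0]
            raise DataValidationError(f"start > end for feature {bad}")
        if (df["chromosome"].astype(str).str.len() == 0).any():
            raise DataValidationError("empty chromosome name in catalog")
        bad_type = set(df["data_type"]) - {EXPRESSION, COPY_NUMBER}
        if bad_type:
            raise DataValidationError(f"unknown data_type values: {sorted(bad_type)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def restrict(self, data_type: str) -> "FeatureCatalog":
        """Sub-catalog of one data type, preserving order."""
        sub = self.entries[self.entries["data_type"] == data_type].reset_index(drop=True)
        return FeatureCatalog(sub)


@dataclass
class ExpressionMatrix:
    """Numeric feature x sample matrix (expression or gene-level CN).

    ``values`` is a DataFrame indexed by feature id with sample-id
    columns; NaN marks a missing cell.  ``is_normalized`` records
    whether per-feature z-scoring has been applied.
    """

    values: pd.DataFrame
    is_normalized: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            raise DataValidationError(f"duplicate feature id {idx[idx.duplicated()][0]}")
        if cols.duplicated().any():
            raise DataValidationError(f"duplicate sample id {cols[cols.duplicated()][0]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataValidationError("matrix contains non-numeric cells")
        if arr.size and np.isinf(arr).any():
            raise DataValidationError("matrix contains non-finite (inf) cells")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass(frozen=True)
class SegmentSet:
    """Segmented copy-number calls: (sample, chromosome, start, end, log_ratio).

    Segments of one sample on one chromosome must be non-overlapping;
    this is validated at construction.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"segment table missing columns: {missing}")
        if (df["start"] > df["end"]).any():
            row = df[df["start"] > df["end"]].iloc[0]
            raise DataValidationError(
                f"segment start > end for sample {row['sample']} "
                f"{row['chromosome']}:{row['start']}-{row['end']}"
            )
        for (sample, chrom), grp in df.groupby(["sample", "chromosome"], sort=False):
            g = grp.sort_values("start")
            prev_end = g["end"].shift(1)
            overlap = g["start"] <= prev_end
            if overlap.any():
                i = int(np.argmax(overlap.to_numpy()))
                a, b = g.iloc[i - 1], g.iloc[i]
                raise DataValidationError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"({a['start']}..{a['end']}) and ({b['start']}..{b['end']})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample"] == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))


@dataclass
class ClassificationResult:
    """Per-sample subtype calls with discriminant scores and posteriors.

    ``discriminant_scores`` and ``posteriors`` are (n_samples, K) arrays
    in ``class_labels`` order; the assigned class minimizes the
    discriminant score, equivalently maximizes the posterior.
    """

    sample_ids: list[str]
    class_labels: list[str]
    assigned_class: np.ndarray  # (n,) of labels
    discriminant_scores: np.ndarray  # (n, K)
    posteriors: np.ndarray  # (n, K)
    n_features_used: int
    seed: int | None = None

    def __post_init__(self) -> None:
        n, k = len(self.sample_ids), len(self.class_labels)
        if self.discriminant_scores.shape != (n, k) or self.posteriors.shape != (n, k):
            raise DataValidationError("score array shapes inconsistent with ids/labels")
        self.validate_posteriors()
        # assignment must agree with argmin of delta
        want = np.asarray(self.class_labels, dtype=object)[
            np.argmin(self.discriminant_scores, axis=1)
        ]
        if n and not (np.asarray(self.assigned_class, dtype=object) == want).all():
            raise DataValidationError("assigned_class inconsistent with discriminant scores")

    def validate_posteriors(self, tol: float = 1e-9) -> None:
        if len(self.sample_ids) == 0:
            return
        if (self.posteriors < -tol).any():
            raise DataValidationError("negative posterior probability")
        sums = self.posteriors.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=tol):
            raise DataValidationError("posteriors do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.posteriors,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"posterior_{c}" for c in self.class_labels],
        )
        df.insert(0, "assigned_class", self.assigned_class)
        df["max_posterior"] = self.posteriors.max(axis=1) if len(self.sample_ids) else []
        return df


# ---------------------------------------------------------------------------
# readers / writers


def _sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path, missing_token: str = "NA", sep: str | None = None
) -> ExpressionMatrix:
    """Read a delimited features x samples matrix.

    First column holds feature ids, first row sample ids.  Cells equal to
    ``missing_token`` are loaded as missing (NaN); any other non-numeric
    cell is an error naming its row and column.
    """
    df = pd.read_csv(path, sep=_sep(path, sep), index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    df.index = df.index.astype(str)
    out = df.replace(missing_token, np.nan)
    try:
        out = out.astype(float)
    except ValueError:
        for col in out.columns:
            for rid, cell in out[col].items():
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise DataValidationError(
                            f"non-numeric cell {cell!r} at feature {rid}, sample {col}"
                        ) from None
        raise
    return ExpressionMatrix(out)


def write_expression_matrix(matrix: ExpressionMatrix, path, missing_token: str = "NA",
                            sep: str | None = None) -> None:
    matrix.values.to_csv(path, sep=_sep(path, sep), na_rep=missing_token,
                         index_label="feature_id")


def read_segments(path, sep: str | None = None) -> SegmentSet:
    """Read a SEG-like table (sample, chromosome, start, end, log_ratio)."""
    df = pd.read_csv(path, sep=_sep(path, sep))
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"chrom": "chromosome", "log2ratio": "log_ratio", "seg.mean": "log_ratio",
              "sample_id": "sample"}
    df = df.rename(columns=rename)
    if df.empty and not set(SEGMENT_COLUMNS) <= set(df.columns):
        df = pd.DataFrame(columns=SEGMENT_COLUMNS)
    df = df[SEGMENT_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["log_ratio"] = df["log_ratio"].astype(float)
    return SegmentSet(df.reset_index(drop=True))


def write_segments(segments: SegmentSet, path, sep: str | None = None) -> None:
    segments.records.to_csv(path, sep=_sep(path, sep), index=False)


def read_feature_catalog(path, sep: str | None = None) -> FeatureCatalog:
    df = pd.read_csv(path, sep=_sep(path, sep))
    df = df[CATALOG_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    for c in ("feature_id", "gene_symbol", "chromosome", "data_type"):
        df[c] = df[c].astype(str)
    return FeatureCatalog(df.reset_index(drop=True))


def write_feature_catalog(catalog: FeatureCatalog, path, sep: str | None = None) -> None:
    catalog.entries.to_csv(path, sep=_sep(path, sep), index=False)


def write_classification(result: ClassificationResult, path, sep: str | None = None) -> None:
    """Write one row per sample: sample_id, assigned_class, K posteriors, max.

    Posterior row sums are re-validated before writing.  Numerics are
    written with enough digits for a lossless (<=1e-12 relative) read-back.
    """
    result.validate_posteriors()
    result.to_frame().to_csv(path, sep=_sep(path, sep), float_format="%.17g")


def read_classification(path, sep: str | None = None) -> ClassificationResult:
    df = pd.read_csv(path, sep=_sep(path, sep), index_col=0)
    post_cols = [c for c in df.columns if c.startswith("posterior_")]
    labels = [c[len("posterior_"):] for c in post_cols]
    posteriors = df[post_cols].to_numpy(float)
    deltas = -2.0 * np.log(np.clip(posteriors, 1e-300, None))  # monotone surrogate
    return ClassificationResult(
        sample_ids=[str(s) for s in df.index],
        class_labels=labels,
        assigned_class=df["assigned_class"].to_numpy(dtype=object),
        discriminant_scores=deltas,
        posteriors=posteriors,
        n_features_used=0,
    )
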