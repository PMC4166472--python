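"""Step 2: per-feature z-score normalization.

Each feature is scaled to zero mean and unit standard deviation within
the dataset at hand (sample sd, n-1 denominator, missing cells
excluded).  Because a z-score is invariant to positive affine
transforms of the raw values, cohorts measured on different platforms
or scales land on the same axis as the reference training
distribution -- this is the whole cross-platform mechanism: both the
reference cohort and any new cohort are z-scored independently.

Zero-variance features carry no information after scaling and are
dropped, with the drop recorded for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataValidationError, ExpressionMatrix

ZERO_VARIANCE_SD = 1e-12


@dataclass
class NormalizationRecord:
    """Per-feature scaling parameters and the features dropped."""

    means: pd.Series
    sds: pd.Series
    n_used: pd.Series
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            raise DataValidationError("retained feature with non-positive sd")
        if set(self.dropped_features) & set(self.means.index):
            raise DataValidationError("dropped and retained feature sets overlap")

    def to_dict(self) -> dict:
        return {
            "features": {
                f: {"mean": float(self.means[f]), "sd": float(self.sds[f]),
                    "n_used": int(self.n_used[f])}
                for f in self.means.index
            },
            "dropped_features": list(self.dropped_features),
        }


def zscore_features(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationRecord]:
    """Scale every feature to a z-score over its non-missing cells.

    Requires at least two samples.  Features whose sd is below the
    zero-variance threshold (1e-12) are dropped and recorded; raising an
    error if nothing would remain.
    """
    if matrix.n_samples < 2:
        raise DataValidationError("z-scoring needs at least 2 samples (sd undefined)")
    vals = matrix.values
    means = vals.mean(axis=1, skipna=True)
    sds = vals.std(axis=1, ddof=1, skipna=True)
    n_used = vals.notna().sum(axis=1)
    keep = (sds > ZERO_VARIANCE_SD) & (n_used >= 2)
    if not keep.any():
        raise DataValidationError("all features have zero variance")
    dropped = list(vals.index[~keep])
    scaled = vals.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    record = NormalizationRecord(
        means=means[keep], sds=sds[keep], n_used=n_used[keep], dropped_features=dropped
    )
    return ExpressionMatrix(scaled, is_normalized=True), record


def apply_normalization(matrix: ExpressionMatrix, record: NormalizationRecord) -> ExpressionMatrix:
    """Apply previously estimated scaling parameters to another matrix."""
    common = [f for f in matrix.feature_ids if f in record.means.index]
    sub = matrix.values.loc[common]
    scaled = sub.sub(record.means[common], axis=0).div(record.sds[common], axis=0)
    return ExpressionMatrix(scaled, is_normalized=True)
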