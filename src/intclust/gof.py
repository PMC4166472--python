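"""Goodness-of-fit diagnostics for a classified cohort.

After classifying a new cohort, a per-subtype quality statistic is
computed: the Pearson correlation between the cohort's subtype-average
expression profile and the reference (unshrunk) centroid of that
subtype, restricted to the features the cohort actually provides.  A
study-level summary averages these correlations over the non-empty
subtypes.  High values mean the new study reproduces the reference
subtype profiles faithfully; values near zero flag cohorts whose
assignments are not supported by the expected expression patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClassificationResult, DataValidationError, ExpressionMatrix, FeatureCatalog
from .nsc import CentroidModel


@dataclass
class GofReport:
    per_class_r: dict[str, float]
    study_gof: float
    n_features_used: int
    n_samples_per_class: dict[str, int]
    absent_classes: dict[str, str] = field(default_factory=dict)  # class -> reason

    def __post_init__(self) -> None:
        for c, r in self.per_class_r.items():
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise DataValidationError(f"correlation out of range for class {c}")

    def to_dict(self) -> dict:
        return {
            "per_class_r": {c: float(r) for c, r in self.per_class_r.items()},
            "study_gof": float(self.study_gof),
            "n_features_used": int(self.n_features_used),
            "n_samples_per_class": {c: int(n) for c, n in self.n_samples_per_class.items()},
            "absent_classes": dict(self.absent_classes),
        }


def average_profiles(matrix: ExpressionMatrix, result: ClassificationResult,
                     catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Class x feature table of subtype-mean expression profiles.

    When a catalog is given, features are ordered by genomic position
    (chromosome, then start) so the table is directly plottable as a
    genome-wide profile.
    """
    assigned = pd.Series(result.assigned_class, index=result.sample_ids)
    classes = [c for c in result.class_labels if (assigned == c).any()]
    rows = {}
    for c in classes:
        samples = assigned.index[assigned == c]
        rows[c] = matrix.values[list(samples)].mean(axis=1, skipna=True)
    table = pd.DataFrame(rows).T
    table.index.name = "class"
    if catalog is not None:
        order = catalog.entries.sort_values(["chromosome", "start"])["feature_id"]
        cols = [f for f in order if f in table.columns]
        table = table[cols]
    return table


def per_class_gof(
    matrix: ExpressionMatrix,
    result: ClassificationResult,
    model: CentroidModel,
    use_shrunken: bool = False,
) -> GofReport:
    """Per-subtype Pearson correlation with the training centroids.

    For each class with at least one assigned sample, correlates the
    cohort's class-mean profile with the model's centroid over the
    shared features.  Classes whose mean profile has zero variance are
    recorded as absent with a reason.  The study-level statistic is the
    unweighted mean over the present classes.
    """
    common = [f for f in model.feature_ids if f in set(matrix.feature_ids)]
    if len(common) < 3:
        raise DataValidationError("need at least 3 shared features for GOF")
    centroids = model.shrunken_centroids() if use_shrunken else model.class_centroids
    pos = {f: i for i, f in enumerate(model.feature_ids)}
    cidx = [pos[f] for f in common]

    assigned = pd.Series(result.assigned_class, index=result.sample_ids)
    per_class: dict[str, float] = {}
    absent: dict[str, str] = {}
    counts: dict[str, int] = {}
    for ki, c in enumerate(model.class_labels):
        samples = assigned.index[assigned == c]
        counts[c] = len(samples)
        if len(samples) == 0:
            absent[c] = "no samples assigned"
            continue
        profile = matrix.values.loc[common, list(samples)].mean(axis=1, skipna=True)
        target = centroids[ki, cidx]
        ok = profile.notna().to_numpy()
        if ok.sum() < 3 or np.std(profile[ok]) == 0 or np.std(target[ok]) == 0:
            absent[c] = "zero-variance or insufficient profile"
            continue
        r, _ = stats.pearsonr(profile.to_numpy()[ok], target[ok])
        per_class[c] = float(r)
    if not per_class:
        raise DataValidationError("no class produced a defined correlation")
    study = float(np.mean(list(per_class.values())))
    return GofReport(
        per_class_r=per_class,
        study_gof=study,
        n_features_used=len(common),
        n_samples_per_class=counts,
        absent_classes=absent,
    )
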