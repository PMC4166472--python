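"""End-to-end classification pipeline.

Glues the three classifier steps together the way a user runs them:
(1) match the study's features against the reference catalog, (2)
z-score each matched feature, (3) re-estimate shrunken centroids
against the reference cohort on the available feature set and assign
subtypes, then compute goodness-of-fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gof import GofReport, per_class_gof
from .io import ClassificationResult, DataValidationError, ExpressionMatrix, FeatureCatalog, SegmentSet
from .matching import (
    MatchReport,
    assemble_combined,
    match_expression_features,
    segments_to_gene_matrix,
)
from .normalization import zscore_features
from .nsc import MIN_FEATURE_FRACTION, CentroidModel, predict, retrain_on_features

MODES = ("expression", "copy_number", "combined")


@dataclass
class ReferenceSet:
    """A normalized, matched reference cohort ready to train against."""

    matrix: ExpressionMatrix  # normalized, catalog-ordered
    labels: pd.Series
    catalog: FeatureCatalog


@dataclass
class StudyClassification:
    result: ClassificationResult
    model: CentroidModel
    match_report: MatchReport
    gof: GofReport


def build_reference(
    expression: ExpressionMatrix,
    labels: pd.Series,
    catalog: FeatureCatalog,
    segments: SegmentSet | None = None,
    mode: str = "expression",
    feature_mode: str = "probe",
) -> ReferenceSet:
    """Match and normalize a reference cohort for a given data mode."""
    matrix = _matched_matrix(expression, segments, catalog, mode, feature_mode)
    normalized, _ = zscore_features(matrix)
    return ReferenceSet(matrix=normalized, labels=labels, catalog=catalog)


def _matched_matrix(expression, segments, catalog, mode, feature_mode) -> ExpressionMatrix:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("expression", "combined"):
        expr, _ = match_expression_features(expression, catalog, mode=feature_mode)
    if mode in ("copy_number", "combined"):
        if segments is None:
            raise DataValidationError(f"mode {mode!r} requires segmented copy-number data")
        cn, _ = segments_to_gene_matrix(segments, catalog)
    if mode == "expression":
        return expr
    if mode == "copy_number":
        return cn
    return assemble_combined(expr, cn)


def classify_study(
    reference: ReferenceSet,
    expression: ExpressionMatrix | None = None,
    segments: SegmentSet | None = None,
    mode: str = "expression",
    feature_mode: str = "gene",
    seed: int = 0,
    min_feature_fraction: float = MIN_FEATURE_FRACTION,
    n_thresholds: int = 30,
    n_folds: int = 10,
) -> StudyClassification:
    """Classify a new study against a reference cohort.

    The study's features are matched to the reference catalog, z-scored
    within the study, and a fresh shrunken-centroid model is
    re-estimated on the reference restricted to the features the study
    provides; samples are then assigned and per-subtype goodness of fit
    is computed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("expression", "combined") and expression is None:
        raise DataValidationError(f"mode {mode!r} requires expression data")
    if mode in ("copy_number", "combined") and segments is None:
        raise DataValidationError(f"mode {mode!r} requires segmented copy-number data")
    if mode == "expression":
        matched, report = match_expression_features(expression, reference.catalog,
                                                    mode=feature_mode)
    elif mode == "copy_number":
        matched, report = segments_to_gene_matrix(segments, reference.catalog)
    else:
        expr, report = match_expression_features(expression, reference.catalog,
                                                 mode=feature_mode)
        cn, _ = segments_to_gene_matrix(segments, reference.catalog,
                                        sample_ids=expr.sample_ids)
        matched = assemble_combined(expr, cn)

    normalized, _ = zscore_features(matched)
    model = retrain_on_features(
        (reference.matrix, reference.labels),
        normalized.feature_ids,
        seed=seed,
        min_feature_fraction=min_feature_fraction,
        n_thresholds=n_thresholds,
        n_folds=n_folds,
    )
    result = predict(model, normalized, min_feature_fraction=min_feature_fraction)
    gof = per_class_gof(normalized, result, model)
    return StudyClassification(result=result, model=model, match_report=report, gof=gof)
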