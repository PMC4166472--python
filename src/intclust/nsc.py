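"""Step 3: nearest-shrunken-centroid classification.

The classifier follows the shrunken-centroid (PAM) scheme.  For feature
j and class k with class means x̄_kj, overall mean x̄_j, pooled
within-class standard deviation s_j and fudge factor s0 (the median of
the s_j), the standardized centroid offset is

    d_kj = (x̄_kj − x̄_j) / (m_k · (s_j + s0)),    m_k = sqrt(1/n_k − 1/n)

Soft-thresholding by Δ gives d'_kj = sign(d_kj)·max(|d_kj| − Δ, 0) and
shrunken centroids x̄'_kj = x̄_j + m_k (s_j + s0) d'_kj.  A sample x is
scored per class by the discriminant

    δ_k(x) = Σ_j (x_j − x̄'_kj)² / (s_j + s0)²  −  2 log π_k

over the features available for that sample, and assigned to the class
minimizing δ_k; posteriors are exp(−δ_k/2) renormalized.  The shrinkage
threshold Δ is chosen by stratified cross-validation on a fixed grid,
so a fixed random seed makes the whole procedure deterministic.

Missing genes on a new platform are handled by re-estimating the
centroids against the reference cohort restricted to the available
feature set (:func:`retrain_on_features`), mirroring how the original
subtyping method accommodates partial panels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import ClassificationResult, DataValidationError, ExpressionMatrix

#: fraction of model features that must be present to predict at all
MIN_FEATURE_FRACTION = 0.5

#: conventions for the class-size factor m_k
M_CONVENTIONS = ("minus", "plus")


@dataclass
class CentroidModel:
    """Trained nearest-shrunken-centroid state.

    Arrays are ordered by ``class_labels`` (rows) and ``feature_ids``
    (columns).  ``threshold`` is the shrinkage Δ currently applied;
    ``d_kj`` holds the unshrunk standardized offsets so the model can be
    re-shrunk without refitting.
    """

    class_labels: list[str]
    class_centroids: np.ndarray  # (K, p) unshrunk x̄_kj
    overall_centroid: np.ndarray  # (p,)
    pooled_sd: np.ndarray  # (p,)
    s0: float
    m_k: np.ndarray  # (K,)
    priors: np.ndarray  # (K,)
    threshold: float
    d_kj: np.ndarray  # (K, p)
    feature_ids: list[str]
    cv_error_curve: list[tuple[float, int]] = field(default_factory=list)
    seed: int | None = None
    m_convention: str = "minus"

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise DataValidationError("class priors must sum to 1")
        if (self.priors <= 0).any():
            raise DataValidationError("class priors must be positive")
        if (self.pooled_sd < 0).any():
            raise DataValidationError("pooled sd must be non-negative")
        if self.s0 <= 0 and (self.pooled_sd > 0).any():
            raise DataValidationError("s0 must be positive")
        if self.threshold < 0:
            raise DataValidationError("shrinkage threshold must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def shrunken_offsets(self, delta: float | None = None) -> np.ndarray:
        """Soft-thresholded offsets d'_kj at Δ (default: the model's own)."""
        d = self.threshold if delta is None else delta
        if d < 0:
            raise DataValidationError("shrinkage threshold must be non-negative")
        return np.sign(self.d_kj) * np.maximum(np.abs(self.d_kj) - d, 0.0)

    def shrunken_centroids(self, delta: float | None = None) -> np.ndarray:
        """x̄'_kj = x̄_j + m_k (s_j + s0) d'_kj."""
        d = self.threshold if delta is None else delta
        if d == 0:
            return self.class_centroids.copy()  # exact no-shrinkage identity
        dp = self.shrunken_offsets(d)
        scale = self.m_k[:, None] * (self.pooled_sd + self.s0)[None, :]
        return self.overall_centroid[None, :] + scale * dp

    def n_active_features(self, delta: float | None = None) -> int:
        """Number of features with a nonzero shrunken offset in any class."""
        return int((np.abs(self.shrunken_offsets(delta)) > 0).any(axis=0).sum())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "class_centroids": self.class_centroids.tolist(),
            "overall_centroid": self.overall_centroid.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": float(self.s0),
            "m_k": self.m_k.tolist(),
            "priors": self.priors.tolist(),
            "threshold": float(self.threshold),
            "d_kj": self.d_kj.tolist(),
            "feature_ids": list(self.feature_ids),
            "cv_error_curve": [[float(t), int(e)] for t, e in self.cv_error_curve],
            "seed": self.seed,
            "m_convention": self.m_convention,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(
            class_labels=list(d["class_labels"]),
            class_centroids=np.asarray(d["class_centroids"], float),
            overall_centroid=np.asarray(d["overall_centroid"], float),
            pooled_sd=np.asarray(d["pooled_sd"], float),
            s0=float(d["s0"]),
            m_k=np.asarray(d["m_k"], float),
            priors=np.asarray(d["priors"], float),
            threshold=float(d["threshold"]),
            d_kj=np.asarray(d["d_kj"], float),
            feature_ids=list(d["feature_ids"]),
            cv_error_curve=[(float(t), int(e)) for t, e in d.get("cv_error_curve", [])],
            seed=d.get("seed"),
            m_convention=d.get("m_convention", "minus"),
        )

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_label_array(labels, sample_ids: list[str]) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(sample_ids).to_numpy(dtype=object)
    if isinstance(labels, dict):
        return np.array([labels[s] for s in sample_ids], dtype=object)
    arr = np.asarray(labels, dtype=object)
    if len(arr) != len(sample_ids):
        raise DataValidationError("labels length does not match sample count")
    return arr


def fit_centroids(
    matrix: ExpressionMatrix,
    labels,
    m_convention: str = "minus",
    seed: int | None = None,
    max_missing_fraction: float = 0.5,
    _min_class_size: int = 2,
) -> CentroidModel:
    """Fit an unshrunk (Δ=0) centroid model on a normalized matrix.

    Every class needs at least two samples.  Features missing in more
    than ``max_missing_fraction`` of samples are dropped with a warning;
    otherwise missing cells are simply excluded from the per-class means
    and pooled dispersions.  Class priors are the empirical frequencies.
    """
    if m_convention not in M_CONVENTIONS:
        raise ValueError(f"unknown m_k convention {m_convention!r}")
    y = _as_label_array(labels, matrix.sample_ids)
    class_labels = sorted(set(y))
    if len(class_labels) < 2:
        raise DataValidationError("need at least 2 classes")
    n = matrix.n_samples
    counts = {c: int((y == c).sum()) for c in class_labels}
    small = [c for c, m in counts.items() if m < _min_class_size]
    if small:
        raise DataValidationError(f"class with <{_min_class_size} samples: {small}")

    vals = matrix.values
    miss_frac = vals.isna().mean(axis=1)
    if (miss_frac > max_missing_fraction).any():
        dropped = list(vals.index[miss_frac > max_missing_fraction])
        warnings.warn(
            f"dropping {len(dropped)} features missing in >"
            f"{max_missing_fraction:.0%} of samples", stacklevel=2,
        )
        vals = vals.loc[miss_frac <= max_missing_fraction]
    feature_ids = list(vals.index)
    X = vals.to_numpy(float)  # (p, n)
    present = ~np.isnan(X)

    K, p = len(class_labels), X.shape[0]
    class_cent = np.empty((K, p))
    ssq_within = np.zeros(p)
    n_used = present.sum(axis=1)
    for ki, c in enumerate(class_labels):
        cols = y == c
        Xc = X[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            class_cent[ki] = np.nanmean(Xc, axis=1)
        resid = Xc - class_cent[ki][:, None]
        ssq_within += np.nansum(resid**2, axis=1)
    class_cent = np.nan_to_num(class_cent, nan=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmean(X, axis=1)
    dof = np.maximum(n_used - K, 1)
    s_j = np.sqrt(ssq_within / dof)
    s0 = float(np.median(s_j))
    if s0 <= 0:
        s0 = 1e-6  # degenerate noiseless input; keeps δ finite

    n_k = np.array([counts[c] for c in class_labels], float)
    if m_convention == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    else:
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    priors = n_k / n
    d_kj = (class_cent - overall[None, :]) / (m_k[:, None] * (s_j + s0)[None, :])

    return CentroidModel(
        class_labels=class_labels,
        class_centroids=class_cent,
        overall_centroid=overall,
        pooled_sd=s_j,
        s0=s0,
        m_k=m_k,
        priors=priors,
        threshold=0.0,
        d_kj=d_kj,
        feature_ids=feature_ids,
        seed=seed,
        m_convention=m_convention,
    )


def shrink(model: CentroidModel, delta: float) -> CentroidModel:
    """Return a copy of the model with shrinkage threshold Δ applied."""
    if delta < 0:
        raise DataValidationError("shrinkage threshold must be non-negative")
    return replace(model, threshold=float(delta))


def _tie_break(delta_row: np.ndarray, priors: np.ndarray) -> int:
    """argmin δ; ties go to the larger prior, then label order."""
    best = np.min(delta_row)
    tied = np.flatnonzero(delta_row == best)
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[np.argmax(priors[tied])])


def predict(
    model: CentroidModel,
    matrix: ExpressionMatrix,
    min_feature_fraction: float = MIN_FEATURE_FRACTION,
) -> ClassificationResult:
    """Score a normalized matrix against the model's shrunken centroids.

    Features absent from the matrix -- or missing in an individual
    sample -- are excluded from that sample's squared-distance sums,
    which are then rescaled by p_model / p_present so discriminants stay
    comparable across samples.  Fails if fewer than
    ``min_feature_fraction`` of the model's features are present.
    """
    common = [f for f in model.feature_ids if f in set(matrix.feature_ids)]
    if len(common) < min_feature_fraction * model.n_features:
        raise DataValidationError(
            f"only {len(common)}/{model.n_features} model features present "
            f"(min fraction {min_feature_fraction}); consider copy-number or "
            "combined mode, or retrain_on_features"
        )
    pos = {f: i for i, f in enumerate(model.feature_ids)}
    idx = [pos[f] for f in common]
    centroids = model.shrunken_centroids()[:, idx]  # (K, q)
    denom = (model.pooled_sd + model.s0)[idx]  # (q,)

    X = matrix.values.loc[common].to_numpy(float).T  # (n, q)
    present = ~np.isnan(X)
    Z = np.where(present, X, 0.0)

    K = model.n_classes
    n, q = X.shape
    delta = np.empty((n, K))
    for k in range(K):
        r = (Z - centroids[k][None, :]) / denom[None, :]
        sq = np.where(present, r**2, 0.0).sum(axis=1)
        n_present = present.sum(axis=1)
        if (n_present == 0).any():
            raise DataValidationError("sample with no observed model features")
        delta[:, k] = sq * (model.n_features / n_present)
    delta -= 2.0 * np.log(model.priors)[None, :]

    shifted = -0.5 * (delta - delta.min(axis=1, keepdims=True))
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)

    pick = np.argmin(delta, axis=1)
    # exact ties: larger prior wins, then label order
    row_min = delta.min(axis=1)
    tie_rows = np.flatnonzero((delta == row_min[:, None]).sum(axis=1) > 1)
    for i in tie_rows:
        pick[i] = _tie_break(delta[i], model.priors)
    labels_arr = np.asarray(model.class_labels, dtype=object)[pick]

    return ClassificationResult(
        sample_ids=matrix.sample_ids,
        class_labels=list(model.class_labels),
        assigned_class=labels_arr,
        discriminant_scores=delta,
        posteriors=post,
        n_features_used=len(common),
        seed=model.seed,
    )


def threshold_grid(model: CentroidModel, n_thresholds: int) -> np.ndarray:
    """Evenly spaced Δ grid over [0, max|d_kj|]."""
    if n_thresholds < 1:
        raise ValueError("need at least one threshold")
    top = float(np.abs(model.d_kj).max()) if model.d_kj.size else 0.0
    return np.linspace(0.0, top, n_thresholds)


def cross_validate_threshold(
    matrix: ExpressionMatrix,
    labels,
    n_thresholds: int = 30,
    n_folds: int = 10,
    seed: int = 0,
    m_convention: str = "minus",
) -> tuple[float, list[tuple[float, int]]]:
    """Pick the shrinkage threshold by stratified cross-validation.

    The grid spans [0, max|d_kj|] of the full-data fit.  Folds are
    stratified by class with ``n_folds`` capped at the smallest class
    size.  Returns the largest grid value attaining the minimal total
    misclassification count (preferring sparser models) together with
    the full error curve.  Identical seeds yield identical folds, curve
    and threshold.
    """
    if n_folds < 2:
        raise DataValidationError("need at least 2 folds")
    y = _as_label_array(labels, matrix.sample_ids)
    full = fit_centroids(matrix, y, m_convention=m_convention, seed=seed)
    grid = threshold_grid(full, n_thresholds)

    smallest = min(int((y == c).sum()) for c in full.class_labels)
    folds = min(n_folds, smallest)
    if folds < 2:
        raise DataValidationError("smallest class too small for cross-validation")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(grid), dtype=int)
    cols = matrix.values.columns
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        train = ExpressionMatrix(matrix.values[cols[train_idx]], is_normalized=True)
        val = ExpressionMatrix(matrix.values[cols[val_idx]], is_normalized=True)
        # a fold can leave a rare class with a single training sample;
        # the within-fold fit tolerates that (its sd contribution is 0)
        sub = fit_centroids(train, y[train_idx], m_convention=m_convention,
                            seed=seed, _min_class_size=1)
        for gi, dlt in enumerate(grid):
            res = predict(shrink(sub, dlt), val, min_feature_fraction=0.0)
            errors[gi] += int((res.assigned_class != y[val_idx]).sum())

    best_err = errors.min()
    best = max(g for g, e in zip(grid, errors) if e == best_err)
    curve = [(float(g), int(e)) for g, e in zip(grid, errors)]
    return float(best), curve


def train(
    matrix: ExpressionMatrix,
    labels,
    n_thresholds: int = 30,
    n_folds: int = 10,
    seed: int = 0,
    m_convention: str = "minus",
) -> CentroidModel:
    """Fit, cross-validate the shrinkage threshold, and shrink."""
    best, curve = cross_validate_threshold(
        matrix, labels, n_thresholds=n_thresholds, n_folds=n_folds, seed=seed,
        m_convention=m_convention,
    )
    model = fit_centroids(matrix, labels, m_convention=m_convention, seed=seed)
    model = shrink(model, best)
    model.cv_error_curve = curve
    return model


def retrain_on_features(
    reference: tuple[ExpressionMatrix, object],
    available_feature_ids,
    seed: int = 0,
    min_feature_fraction: float = MIN_FEATURE_FRACTION,
    n_thresholds: int = 30,
    n_folds: int = 10,
    m_convention: str = "minus",
) -> CentroidModel:
    """Re-estimate centroids against the reference cohort on a feature subset.

    This is how missing genes on a new platform are accommodated: the
    whole training procedure (fit, cross-validated threshold, shrink) is
    re-run on the reference expression matrix restricted to the features
    the new study actually provides.
    """
    ref_matrix, ref_labels = reference
    avail = set(available_feature_ids)
    keep = [f for f in ref_matrix.feature_ids if f in avail]
    if len(keep) < min_feature_fraction * ref_matrix.n_features:
        raise DataValidationError(
            f"only {len(keep)}/{ref_matrix.n_features} reference features "
            f"available (min fraction {min_feature_fraction}); consider "
            "copy-number or combined mode"
        )
    sub = ExpressionMatrix(ref_matrix.values.loc[keep], is_normalized=ref_matrix.is_normalized)
    return train(sub, ref_labels, n_thresholds=n_thresholds, n_folds=n_folds,
                 seed=seed, m_convention=m_convention)
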