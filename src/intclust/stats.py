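"""Comparative evaluation statistics.

Covers the statistics used to compare subtype labelings and quantify
what a labeling explains: cross-tabulated agreement with Cohen's kappa
(observed agreement corrected for the agreement expected from the
marginals alone), event-rate summaries from printed counts, per-gene
one-way ANOVA adjusted R², and the comparison of two labelings by the
mean difference in adjusted R² over a gene list with a percentile
bootstrap confidence interval (resampling genes, samples fixed).
Study-level estimates can be pooled by a sample-size-weighted mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataValidationError, ExpressionMatrix


@dataclass
class AgreementReport:
    contingency: pd.DataFrame  # A-labels x B-labels counts
    percent_agreement: float  # 0..100
    kappa: float
    expected_agreement_pe: float  # 0..1

    def to_dict(self) -> dict:
        return {
            "contingency": {
                str(a): {str(b): int(v) for b, v in row.items()}
                for a, row in self.contingency.iterrows()
            },
            "percent_agreement": float(self.percent_agreement),
            "kappa": float(self.kappa),
            "expected_agreement_pe": float(self.expected_agreement_pe),
        }


@dataclass
class ExplainedVariationReport:
    per_gene_adj_r2: pd.DataFrame  # gene x {labeling_a, labeling_b}
    mean_delta: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    study_weight: int  # n samples

    def to_dict(self) -> dict:
        return {
            "per_gene_adj_r2": {
                g: {"labeling_a": float(r["labeling_a"]), "labeling_b": float(r["labeling_b"])}
                for g, r in self.per_gene_adj_r2.iterrows()
            },
            "mean_delta": float(self.mean_delta),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_bootstrap": int(self.n_bootstrap),
            "study_weight": int(self.study_weight),
        }


def agreement(labels_a, labels_b) -> AgreementReport:
    """Cross-tabulate two labelings and compute Cohen's kappa.

    p_o is the fraction of identically labeled samples, p_e the chance
    agreement Σ_c marginal_a(c)·marginal_b(c) over the shared label
    space, and kappa = (p_o − p_e)/(1 − p_e).  Disjoint label spaces
    give 0% agreement with a warning.
    """
    a = np.asarray(list(labels_a), dtype=object)
    b = np.asarray(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise DataValidationError("labelings differ in length")
    if len(a) == 0:
        raise DataValidationError("empty labelings")
    la, lb = sorted(set(a)), sorted(set(b))
    if not set(la) & set(lb):
        warnings.warn("label spaces are disjoint; agreement is 0", stacklevel=2)
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    table = table.reindex(index=la, columns=lb, fill_value=0)
    n = len(a)
    p_o = float((a == b).mean())
    shared = sorted(set(la) & set(lb))
    p_e = sum(
        (table.loc[c].sum() / n) * (table[c].sum() / n) for c in shared
    )
    p_e = float(p_e)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(
        contingency=table,
        percent_agreement=100.0 * p_o,
        kappa=float(kappa),
        expected_agreement_pe=p_e,
    )


def proportion_from_counts(events: int, total: int, digits: int = 0) -> tuple[float, float]:
    """Event rate as a percentage: (display-rounded, exact).

    Display rounding is round-half-away-from-zero to ``digits`` decimal
    places, matching how such rates are conventionally printed
    (e.g. 45/121 -> 37).
    """
    if total <= 0:
        raise DataValidationError("total must be positive")
    if not 0 <= events <= total:
        raise DataValidationError("events must lie in [0, total]")
    exact = 100.0 * events / total
    scale = 10**digits
    display = math.floor(abs(exact) * scale + 0.5) / scale * (1 if exact >= 0 else -1)
    return display, exact


def anova_adjusted_r2(y, groups) -> float:
    """Adjusted R² of a one-way ANOVA of y on group membership.

    R² = 1 − SS_within/SS_total; adjusted R² = 1 − (1−R²)(n−1)/(n−k).
    Requires n > k ≥ 2 non-empty groups and non-zero total variance.
    """
    yv = np.asarray(y, float)
    g = np.asarray(list(groups), dtype=object)
    if len(yv) != len(g):
        raise DataValidationError("y and groups differ in length")
    levels = sorted(set(g))
    k, n = len(levels), len(yv)
    if k < 2:
        raise DataValidationError("need at least 2 groups")
    if n <= k:
        raise DataValidationError("need more samples than groups")
    grand = yv.mean()
    ss_total = float(((yv - grand) ** 2).sum())
    if ss_total == 0:
        raise DataValidationError("zero total variance")
    ss_within = 0.0
    for lev in levels:
        sub = yv[g == lev]
        ss_within += float(((sub - sub.mean()) ** 2).sum())
    r2 = 1.0 - ss_within / ss_total
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def explained_variation_comparison(
    expr: ExpressionMatrix,
    labels_a,
    labels_b,
    gene_list: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExplainedVariationReport:
    """Compare how well two labelings explain expression of a gene list.

    Per gene, fits the one-way ANOVA under each labeling and takes the
    difference in adjusted R² (labeling A minus labeling B);
    ``mean_delta`` averages this over genes.  The confidence interval is
    a percentile bootstrap over genes (samples held fixed), using order
    statistics at ranks ⌈α/2·B⌉ and ⌈(1−α/2)·B⌉, deterministic under a
    fixed seed.
    """
    if not gene_list:
        raise DataValidationError("empty gene list")
    missing = [g for g in gene_list if g not in set(expr.feature_ids)]
    if missing:
        raise DataValidationError(f"genes not in expression matrix: {missing[:5]}")
    ya = _align(labels_a, expr.sample_ids)
    yb = _align(labels_b, expr.sample_ids)

    rows = {}
    for g in gene_list:
        vals = expr.values.loc[g]
        ok = vals.notna().to_numpy()
        rows[g] = {
            "labeling_a": anova_adjusted_r2(vals.to_numpy()[ok], ya[ok]),
            "labeling_b": anova_adjusted_r2(vals.to_numpy()[ok], yb[ok]),
        }
    table = pd.DataFrame(rows).T
    deltas = (table["labeling_a"] - table["labeling_b"]).to_numpy()
    mean_delta = float(deltas.mean())

    rng = np.random.default_rng(seed)
    G = len(deltas)
    boot = np.array([
        deltas[rng.integers(0, G, size=G)].mean() for _ in range(n_bootstrap)
    ])
    boot.sort()
    lo_rank = max(math.ceil(alpha / 2 * n_bootstrap), 1)
    hi_rank = min(math.ceil((1 - alpha / 2) * n_bootstrap), n_bootstrap)
    ci_low, ci_high = float(boot[lo_rank - 1]), float(boot[hi_rank - 1])
    return ExplainedVariationReport(
        per_gene_adj_r2=table,
        mean_delta=mean_delta,
        ci_low=ci_low,
        ci_high=ci_high,
        n_bootstrap=n_bootstrap,
        study_weight=expr.n_samples,
    )


def weighted_mean_across_studies(per_study: list[tuple[float, int]]) -> float:
    """Sample-size-weighted mean of per-study estimates: Σ(e·n)/Σn."""
    if not per_study:
        raise DataValidationError("no studies supplied")
    if any(n <= 0 for _, n in per_study):
        raise DataValidationError("study sizes must be positive")
    num = sum(e * n for e, n in per_study)
    den = sum(n for _, n in per_study)
    return float(num / den)


def _align(labels, sample_ids: list[str]) -> np.ndarray:
    if isinstance(labels, pd.Series):
        out = labels.reindex(sample_ids)
        if out.isna().any():
            raise DataValidationError("labeling does not cover all samples")
        return out.to_numpy(dtype=object)
    if isinstance(labels, dict):
        try:
            return np.array([labels[s] for s in sample_ids], dtype=object)
        except KeyError as e:
            raise DataValidationError(f"labeling missing sample {e}") from None
    arr = np.asarray(list(labels), dtype=object)
    if len(arr) != len(sample_ids):
        raise DataValidationError("labeling length does not match sample count")
    return arr
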