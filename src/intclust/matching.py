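"""Step 1 of the classifier: feature matching.

A new dataset rarely provides exactly the reference panel of features.
Expression features are reconciled with the catalog either by probe
name (exact id equality) or by gene name (dataset rows sharing a gene
symbol are averaged).  Segmented copy-number calls are summarized to
gene level by genomic position.  Matched matrices are always returned
in catalog order so downstream centroids line up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    COPY_NUMBER,
    EXPRESSION,
    DataValidationError,
    ExpressionMatrix,
    FeatureCatalog,
    SegmentSet,
)

#: how a segment's log-ratios are summarized over a gene span
SEGMENT_RULES = ("weighted_mean", "midpoint")


@dataclass
class MatchReport:
    """Book-keeping for a matching pass: what matched, what did not."""

    n_catalog: int
    n_matched: int
    unmatched_catalog_ids: list[str]
    ambiguous: list[tuple[str, list[str]]] = field(default_factory=list)
    match_mode: str = "probe"

    def __post_init__(self) -> None:
        if self.n_matched + len(self.unmatched_catalog_ids) != self.n_catalog:
            raise DataValidationError("matched + unmatched must partition the catalog")

    def to_dict(self) -> dict:
        return {
            "n_catalog": self.n_catalog,
            "n_matched": self.n_matched,
            "unmatched_catalog_ids": list(self.unmatched_catalog_ids),
            "ambiguous": [[cid, list(c)] for cid, c in self.ambiguous],
            "match_mode": self.match_mode,
        }


def match_expression_features(
    matrix: ExpressionMatrix,
    catalog: FeatureCatalog,
    mode: str = "gene",
    gene_of_row: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, MatchReport]:
    """Match dataset rows to the expression catalog by probe or gene name.

    In ``probe`` mode a catalog entry matches only a dataset row with the
    identical feature id.  In ``gene`` mode dataset rows are keyed by
    gene name -- the row id itself, or ``gene_of_row[row_id]`` when the
    dataset carries probe ids with a separate probe-to-gene map -- and
    all rows mapping to one catalog gene symbol are aggregated by their
    per-sample arithmetic mean (missing cells excluded).  Matching is
    case-sensitive exact equality; the output contains exactly the
    matched catalog entries, in catalog order.
    """
    if mode not in ("probe", "gene"):
        raise ValueError(f"unknown match mode {mode!r}")
    cat = catalog.restrict(EXPRESSION).entries
    if mode == "gene" and (cat["gene_symbol"].str.len() == 0).any():
        raise DataValidationError("gene mode requires non-empty gene symbols in catalog")

    rows: dict[str, np.ndarray] = {}
    matched_ids: list[str] = []
    unmatched: list[str] = []
    ambiguous: list[tuple[str, list[str]]] = []

    if mode == "probe":
        have = set(matrix.feature_ids)
        for fid in cat["feature_id"]:
            if fid in have:
                rows[fid] = matrix.values.loc[fid].to_numpy(float)
                matched_ids.append(fid)
            else:
                unmatched.append(fid)
    else:
        gmap = gene_of_row or {}
        genes = pd.Index([gmap.get(r, r) for r in matrix.feature_ids])
        members: dict[str, list[str]] = {}
        for rid, g in zip(matrix.feature_ids, genes):
            members.setdefault(g, []).append(rid)
        means = matrix.values.groupby(genes).mean()
        for fid, g in zip(cat["feature_id"], cat["gene_symbol"]):
            if g in means.index:
                rows[fid] = means.loc[g].to_numpy(float)
                matched_ids.append(fid)
                if len(members[g]) > 1:
                    ambiguous.append((fid, list(members[g])))
            else:
                unmatched.append(fid)

    if not matched_ids:
        raise DataValidationError("no features matched")
    out = pd.DataFrame(
        np.vstack([rows[f] for f in matched_ids]),
        index=pd.Index(matched_ids, name="feature_id"),
        columns=matrix.sample_ids,
    )
    report = MatchReport(
        n_catalog=len(cat),
        n_matched=len(matched_ids),
        unmatched_catalog_ids=unmatched,
        ambiguous=ambiguous,
        match_mode=mode,
    )
    return ExpressionMatrix(out, is_normalized=matrix.is_normalized), report


def segments_to_gene_matrix(
    segments: SegmentSet,
    catalog: FeatureCatalog,
    rule: str = "weighted_mean",
    sample_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, MatchReport]:
    """Summarize segmented copy-number calls to catalog genes by position.

    ``weighted_mean`` (default): overlap-length-weighted mean of the
    log-ratios of all segments intersecting the gene span (1-based closed
    coordinates).  ``midpoint``: log-ratio of the segment covering the
    gene midpoint.  Genes with no overlapping segment in a sample are
    missing; genes unmatched in every sample are reported.
    """
    if rule not in SEGMENT_RULES:
        raise ValueError(f"unknown segment rule {rule!r}")
    cat = catalog.restrict(COPY_NUMBER).entries
    if cat[["start", "end"]].isna().any().any():
        raise DataValidationError("copy-number catalog entry lacking coordinates")
    samples = sample_ids if sample_ids is not None else segments.sample_ids
    values = np.full((len(cat), len(samples)), np.nan)
    sample_col = {s: j for j, s in enumerate(samples)}

    gene_rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in cat.groupby("chromosome", sort=False):
        gene_rows[chrom] = (
            grp.index.to_numpy(),
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
        )

    for (sample, chrom), grp in segments.records.groupby(["sample", "chromosome"], sort=False):
        j = sample_col.get(sample)
        genes = gene_rows.get(chrom)
        if j is None or genes is None:
            continue
        rows, gs, ge = genes
        s = grp["start"].to_numpy()[None, :]  # (1, n_seg)
        e = grp["end"].to_numpy()[None, :]
        lr = grp["log_ratio"].to_numpy()
        if rule == "midpoint":
            mid = ((gs + ge) // 2)[:, None]
            hit = (s <= mid) & (mid <= e)  # (n_gene, n_seg)
            any_hit = hit.any(axis=1)
            first = hit.argmax(axis=1)
            values[rows[any_hit], j] = lr[first[any_hit]]
        else:
            ov = np.minimum(e, ge[:, None]) - np.maximum(s, gs[:, None]) + 1
            w = np.maximum(ov, 0).astype(float)
            tot = w.sum(axis=1)
            covered = tot > 0
            values[rows[covered], j] = (w @ lr)[covered] / tot[covered]

    all_missing = np.isnan(values).all(axis=1)
    unmatched = list(cat["feature_id"][all_missing])
    matched_mask = ~all_missing
    out = pd.DataFrame(
        values[matched_mask],
        index=pd.Index(cat["feature_id"][matched_mask], name="feature_id"),
        columns=samples,
    )
    report = MatchReport(
        n_catalog=len(cat),
        n_matched=int(matched_mask.sum()),
        unmatched_catalog_ids=unmatched,
        match_mode="position",
    )
    return ExpressionMatrix(out), report


EXPR_PREFIX = "expr:"
CN_PREFIX = "cn:"


def assemble_combined(expr: ExpressionMatrix, cn: ExpressionMatrix) -> ExpressionMatrix:
    """Row-stack expression and gene-level CN into one feature space.

    Feature ids get ``expr:`` / ``cn:`` prefixes so the union is unique;
    sample order is taken from the expression matrix.  The two inputs
    must cover the same sample set.
    """
    a, b = set(expr.sample_ids), set(cn.sample_ids)
    if a != b:
        diff = sorted(a ^ b)
        raise DataValidationError(f"sample sets differ: {diff}")
    top = expr.values.copy()
    top.index = [EXPR_PREFIX + f for f in expr.feature_ids]
    bottom = cn.values[expr.sample_ids].copy()
    bottom.index = [CN_PREFIX + f for f in cn.feature_ids]
    stacked = pd.concat([top, bottom])
    stacked.index.name = "feature_id"
    return ExpressionMatrix(stacked, is_normalized=expr.is_normalized and cn.is_normalized)


def split_combined(combined: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Inverse of :func:`assemble_combined`."""
    is_expr = [f.startswith(EXPR_PREFIX) for f in combined.feature_ids]
    expr = combined.values[np.array(is_expr)].copy()
    cn = combined.values[~np.array(is_expr)].copy()
    expr.index = [f[len(EXPR_PREFIX):] for f in expr.index]
    cn.index = [f[len(CN_PREFIX):] for f in cn.index]
    expr.index.name = cn.index.name = "feature_id"
    return ExpressionMatrix(expr), ExpressionMatrix(cn)
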