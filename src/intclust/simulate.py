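"""Synthetic subtype-structured cohorts.

Real training data for integrative-cluster subtyping are
controlled-access, so the pipeline is exercised on simulated cohorts
that reproduce the statistical structure the classifier assumes: each
of (by default) ten subtypes carries a characteristic archetype of
locus-level copy-number states which exert a cis dosage effect on the
expression of the genes at those loci, on top of a subtype-specific
basal expression shift and Gaussian measurement noise.

Class frequencies default to an uneven distribution whose rarest
subtype is 4.5% of tumors, echoing the discovery-cohort composition.
Default archetypes loosely echo described subtype biology -- one class
defined by a focal high-level amplicon (an 11q13/14-like event), one by
a 17q23-like amplicon, one by an ERBB2-like amplicon, and one entirely
CNA-devoid flat class -- without claiming fidelity to the real subtype
profiles.  Genes live on a synthetic 22-chromosome grid so that
position-based segment matching is exercised end to end.

A platform-perturbation step emulates study-to-study variability:
feature dropout (e.g. a panel providing only 579 of 612 genes),
per-feature affine rescaling, and added noise.  All generation is fully
reproducible from seeds.
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

#: log-ratio emitted per unit copy-number state in {-1, 0, +1, +2}
STATE_LOG_RATIO = 0.5

#: default subtype frequencies; the rarest class (IC2) is 4.5%
DEFAULT_FREQUENCIES = (0.08, 0.045, 0.15, 0.16, 0.09, 0.055, 0.10, 0.14, 0.07, 0.11)

CNA_STATES = (-1, 0, 1, 2)
N_CHROMOSOMES = 22
GENE_LENGTH = 5_000
GENE_SPACING = 10_000
LOCUS_SPACING = 1_000_000


def default_archetypes(n_classes: int = 10, n_loci: int = 34) -> np.ndarray:
    """Deterministic class x locus matrix of copy-number states.

    Each non-flat class gets one focal high-level amplification (+2),
    two single-copy gains (+1) and one deletion (-1) at class-specific
    loci; class index 3 is the CNA-devoid flat class.  Rows are
    guaranteed distinct.
    """
    if n_loci < n_classes:
        raise DataValidationError("need at least one locus per class")
    arch = np.zeros((n_classes, n_loci), dtype=int)
    for k in range(n_classes):
        if k == 3 and n_classes >= 4:
            continue  # CNA-devoid class
        arch[k, k % n_loci] = 2
        arch[k, (2 * k + 7) % n_loci] = 1
        arch[k, (3 * k + 11) % n_loci] = 1
        arch[k, (5 * k + 17) % n_loci] = -1
        arch[k, k % n_loci] = 2  # focal amplicon wins any collision
    if len({tuple(r) for r in arch}) != n_classes:
        raise DataValidationError("archetype rows not distinct")
    return arch


@dataclass
class CohortConfig:
    """Generation parameters for a synthetic cohort."""

    n_samples: int = 1000
    n_classes: int = 10
    class_frequencies: tuple = DEFAULT_FREQUENCIES
    n_loci: int = 34
    genes_per_locus: int = 18
    cna_archetypes: np.ndarray | None = None
    dosage_effect: float = 1.0  # expression units per copy-number state unit
    basal_shift_sd: float = 0.5
    noise_sd: float = 1.0
    deviation_rate: float = 0.02  # per-locus chance of a non-archetype state
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.class_frequencies, float)
        if len(freqs) != self.n_classes:
            raise DataValidationError("class_frequencies length != n_classes")
        if not np.isclose(freqs.sum(), 1.0) or (freqs <= 0).any():
            raise DataValidationError("class_frequencies must be a positive simplex vector")
        if self.cna_archetypes is None:
            self.cna_archetypes = default_archetypes(self.n_classes, self.n_loci)
        arch = np.asarray(self.cna_archetypes)
        if arch.shape != (self.n_classes, self.n_loci):
            raise DataValidationError("archetype matrix shape != (n_classes, n_loci)")
        if len({tuple(r) for r in arch}) != self.n_classes:
            raise DataValidationError("archetype rows must be distinct")

    @property
    def n_genes(self) -> int:
        return self.n_loci * self.genes_per_locus

    @property
    def class_labels(self) -> list[str]:
        return [f"IC{k + 1}" for k in range(self.n_classes)]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    segments: SegmentSet
    catalog: FeatureCatalog
    true_labels: pd.Series
    config: CohortConfig | None = None


def build_catalog(config: CohortConfig) -> FeatureCatalog:
    """Deterministic gene placement on 22 pseudo-chromosomes.

    Loci are assigned round-robin to chromosomes; within a chromosome
    consecutive loci are spaced 1 Mb apart and the genes of a locus sit
    on a 10 kb grid, each spanning 5 kb (1-based closed intervals).
    Every gene appears twice: as an expression feature (id = gene
    symbol) and as a copy-number feature (id prefixed ``CN_``).
    """
    rows = []
    for locus in range(config.n_loci):
        chrom = f"chr{(locus % N_CHROMOSOMES) + 1}"
        locus_rank = locus // N_CHROMOSOMES
        base = locus_rank * LOCUS_SPACING + 1
        for j in range(config.genes_per_locus):
            g = locus * config.genes_per_locus + j
            start = base + j * GENE_SPACING
            end = start + GENE_LENGTH - 1
            symbol = f"G{g:04d}"
            rows.append((symbol, symbol, chrom, start, end, EXPRESSION))
            rows.append((f"CN_{symbol}", symbol, chrom, start, end, COPY_NUMBER))
    df = pd.DataFrame(rows, columns=[
        "feature_id", "gene_symbol", "chromosome", "start", "end", "data_type"])
    return FeatureCatalog(df)


def _basal_shifts(config: CohortConfig) -> np.ndarray:
    """Subtype basal expression offsets (K x genes), fixed by config.seed.

    These belong to the reference model, not to an individual cohort
    draw: every cohort generated from the same config shares them, so a
    classifier trained on one cohort transfers to another.
    """
    rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, config.basal_shift_sd, size=(config.n_classes, config.n_genes))


def _locus_spans(config: CohortConfig) -> list[tuple[str, int, int]]:
    spans = []
    for locus in range(config.n_loci):
        chrom = f"chr{(locus % N_CHROMOSOMES) + 1}"
        locus_rank = locus // N_CHROMOSOMES
        base = locus_rank * LOCUS_SPACING + 1
        last_start = base + (config.genes_per_locus - 1) * GENE_SPACING
        spans.append((chrom, base, last_start + GENE_LENGTH - 1))
    return spans


def make_reference_cohort(
    config: CohortConfig,
    n_samples: int | None = None,
    sample_seed: int | None = None,
) -> SyntheticCohort:
    """Draw a cohort from the reference model defined by ``config``.

    Per sample: a class is drawn from the class frequencies; locus
    states are the class archetype with rare random deviations;
    expression of each gene is dosage_effect x locus state + the class
    basal shift + Gaussian noise; one segment per locus is emitted with
    log-ratio 0.5 x state, so gene-level copy number recomputed from the
    segments inverts exactly to the realized locus states.

    ``sample_seed`` (default: ``config.seed``) controls the sampling
    randomness only; the class model itself is fixed by ``config.seed``.
    """
    n = config.n_samples if n_samples is None else n_samples
    rng = np.random.default_rng(config.seed if sample_seed is None else sample_seed)
    freqs = np.asarray(config.class_frequencies, float)
    arch = np.asarray(config.cna_archetypes, int)
    basal = _basal_shifts(config)

    classes = rng.choice(config.n_classes, size=n, p=freqs)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = pd.Series(
        [config.class_labels[k] for k in classes], index=sample_ids, name="true_label"
    )

    # realized locus states: archetype plus rare deviations
    states = arch[classes].copy()  # (n, n_loci)
    if config.deviation_rate > 0:
        flip = rng.random(states.shape) < config.deviation_rate
        random_states = rng.choice(CNA_STATES, size=states.shape)
        states = np.where(flip, random_states, states)

    gene_locus = np.repeat(np.arange(config.n_loci), config.genes_per_locus)
    dosage = config.dosage_effect * states[:, gene_locus]  # (n, genes)
    expr = dosage + basal[classes] + rng.normal(0.0, config.noise_sd, size=dosage.shape)

    gene_ids = [f"G{g:04d}" for g in range(config.n_genes)]
    expression = ExpressionMatrix(
        pd.DataFrame(expr.T, index=pd.Index(gene_ids, name="feature_id"),
                     columns=sample_ids)
    )

    spans = _locus_spans(config)
    seg_rows = []
    for i, sid in enumerate(sample_ids):
        for locus, (chrom, start, end) in enumerate(spans):
            seg_rows.append(
                (sid, chrom, start, end, STATE_LOG_RATIO * states[i, locus])
            )
    segments = SegmentSet(pd.DataFrame(
        seg_rows, columns=["sample", "chromosome", "start", "end", "log_ratio"]))

    return SyntheticCohort(
        expression=expression,
        segments=segments,
        catalog=build_catalog(config),
        true_labels=labels,
        config=config,
    )


def perturb_platform(
    cohort: SyntheticCohort,
    keep_fraction: float = 1.0,
    feature_scale_sd: float = 0.0,
    extra_noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Emulate measuring the same samples on a different platform.

    Retains a random feature subset of size ceil(keep_fraction x p),
    rescales each retained feature by a lognormal(0, feature_scale_sd)
    factor, shifts it by a normal(0, feature_scale_sd) offset, and adds
    Gaussian noise.  True labels, segments and catalog are unchanged.
    """
    if not 0 < keep_fraction <= 1:
        raise DataValidationError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    vals = cohort.expression.values
    p = vals.shape[0]
    n_keep = int(np.ceil(keep_fraction * p))
    keep_idx = np.sort(rng.choice(p, size=n_keep, replace=False))
    sub = vals.iloc[keep_idx].copy()
    if feature_scale_sd > 0:
        scale = rng.lognormal(0.0, feature_scale_sd, size=n_keep)
        shift = rng.normal(0.0, feature_scale_sd, size=n_keep)
        sub = sub.mul(scale, axis=0).add(shift, axis=0)
    if extra_noise_sd > 0:
        sub = sub + rng.normal(0.0, extra_noise_sd, size=sub.shape)
    return SyntheticCohort(
        expression=ExpressionMatrix(sub),
        segments=cohort.segments,
        catalog=cohort.catalog,
        true_labels=cohort.true_labels,
        config=cohort.config,
    )


def make_study_panel(
    config: CohortConfig,
    n_studies: int,
    size_range: tuple[int, int] = (300, 800),
    keep_fraction_range: tuple[float, float] = (0.8, 1.0),
    scale_sd_range: tuple[float, float] = (0.0, 0.2),
    noise_sd_range: tuple[float, float] = (0.0, 0.3),
    seed: int = 0,
) -> list[SyntheticCohort]:
    """Independent perturbed cohorts drawn from one reference model.

    Each study draws fresh samples from the model defined by ``config``
    (so the subtype profiles are shared across studies), with its size
    and perturbation parameters sampled uniformly from the given ranges.
    Reproducible from ``seed``.
    """
    if n_studies < 1:
        raise DataValidationError("need at least one study")
    lo, hi = size_range
    if not (0 < lo <= hi):
        raise DataValidationError("invalid size range")
    for name, (a, b) in [("keep_fraction", keep_fraction_range),
                         ("scale_sd", scale_sd_range), ("noise_sd", noise_sd_range)]:
        if a > b or a < 0:
            raise DataValidationError(f"invalid {name} range")
    rng = np.random.default_rng(seed)
    panel = []
    for _ in range(n_studies):
        n = int(rng.integers(lo, hi + 1))
        cohort = make_reference_cohort(
            config, n_samples=n, sample_seed=int(rng.integers(2**31)))
        cohort = perturb_platform(
            cohort,
            keep_fraction=float(rng.uniform(*keep_fraction_range)),
            feature_scale_sd=float(rng.uniform(*scale_sd_range)),
            extra_noise_sd=float(rng.uniform(*noise_sd_range)),
            seed=int(rng.integers(2**31)),
        )
        panel.append(cohort)
    return panel
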