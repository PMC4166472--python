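import numpy as np
import pandas as pd
import pytest

import intclust as ic


def make_matrix(values, feature_ids=None, sample_ids=None, normalized=False):
    arr = np.asarray(values, float)
    p, n = arr.shape
    return ic.ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=pd.Index(feature_ids or [f"F{i}" for i in range(p)], name="feature_id"),
            columns=sample_ids or [f"S{i}" for i in range(n)],
        ),
        is_normalized=normalized,
    )


def random_fixture(rng, p=None, n=None, k=None):
    """Random small classification fixture: normalized matrix + labels."""
    p = p or int(rng.integers(2, 6))
    k = k or int(rng.integers(2, 5))
    # every class needs >=2 samples
    counts = rng.integers(2, 6, size=k)
    n = int(counts.sum())
    labels = np.repeat([f"C{i}" for i in range(k)], counts)
    rng.shuffle(labels)
    X = rng.normal(size=(p, n)) + rng.normal(scale=2.0, size=(p, 1))
    return make_matrix(X, normalized=True), list(labels)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact synthetic cohort used across tests (fast to generate)."""
    config = ic.CohortConfig(
        n_samples=240, n_classes=4, class_frequencies=(0.4, 0.3, 0.2, 0.1),
        n_loci=8, genes_per_locus=6, seed=11,
    )
    return ic.make_reference_cohort(config)


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    return ic.build_reference(
        small_cohort.expression, small_cohort.true_labels, small_cohort.catalog,
        segments=small_cohort.segments, mode="expression", feature_mode="probe",
    )


@pytest.fixture(scope="session")
def small_model(small_reference):
    return ic.train(small_reference.matrix, small_reference.labels, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition reference cohort (10 subtypes, 612 genes)."""
    return ic.make_reference_cohort(ic.CohortConfig(n_samples=400, seed=0))


@pytest.fixture(scope="session")
def default_reference(default_cohort):
    return ic.build_reference(
        default_cohort.expression, default_cohort.true_labels, default_cohort.catalog)


@pytest.fixture(scope="session")
def default_model(default_reference):
    return ic.train(default_reference.matrix, default_reference.labels, seed=0)
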