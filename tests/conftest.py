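import numpy as np
import pytest

from sbce_bayes import Dataset, Reading, build_reference_fixture, canonical_schema


@pytest.fixture(scope="session")
def schema():
    return canonical_schema()


@pytest.fixture(scope="session")
def fixture_dataset():
    """The 81-reading synthetic reference cohort, seed 0."""
    return build_reference_fixture(seed=0)


def make_dataset(rows, schema=None, task="severity"):
    """Build a labelled Dataset from (values, class_code) pairs.

    Class code 1 maps to Marsh 0 / SNVA, class 2 to Marsh 3b / CD, so the
    same rows are usable under either task.
    """
    schema = schema or canonical_schema()
    readings = []
    for idx, (values, c) in enumerate(rows):
        readings.append(
            Reading(
                values=tuple(values),
                marsh_label="0" if c == 1 else "3b",
                disease_label="SNVA" if c == 1 else "CD",
                patient_id=f"T{idx:03d}",
            )
        )
    return Dataset(schema=schema, readings=tuple(readings))


def random_rows(rng, n, schema=None, p_class1=0.5):
    """Random (values, class) rows uniform over the feature space."""
    schema = schema or canonical_schema()
    rows = []
    for _ in range(n):
        values = tuple(int(rng.integers(1, K + 1)) for K in schema.level_counts)
        rows.append((values, 1 if rng.random() < p_class1 else 2))
    return rows


def brute_force_posterior(rows, c, i, k, K, alpha=1.0):
    """Independent tally oracle for the posterior-predictive probability.

    Walks the raw rows, counts class-c readings and those with level k on
    feature i (1-based), and forms (N_k + alpha) / (N + K * alpha).
    """
    n_class = sum(1 for _, cc in rows if cc == c)
    n_k = sum(1 for values, cc in rows if cc == c and values[i - 1] == k)
    return (n_k + alpha) / (n_class + K * alpha)
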