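import numpy as np
import pandas as pd
import pytest

from hetassoc.io import MISSING, GenotypeMatrix, SampleTable, VARIANT_COLUMNS


def make_matrix(calls, chroms=None, samples=None):
    """Build a GenotypeMatrix from a nested list / array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chroms is None:
        chroms = [str(j % 22 + 1) for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
        }
    )[VARIANT_COLUMNS]
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, calls)


def make_samples(rows):
    """rows: list of (sample_id, status, joint, age, sex, bmi, diabetes)."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "status", "joint", "age", "sex", "bmi", "diabetes"],
    )
    return SampleTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    """50 samples x 200 variants with ~2% missingness, all autosomal."""
    calls = rng.integers(0, 3, size=(50, 200)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.02] = MISSING
    return make_matrix(calls)


@pytest.fixture
def toy_cohort():
    """6-sample cohort with a fully populated sample table."""
    g = make_matrix(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 0, 2, 1],
            [0, 0, 1, 1, 2],
            [2, 1, 1, 0, 0],
            [1, 2, 0, 1, 1],
            [0, 1, 1, 2, 0],
        ]
    )
    s = make_samples(
        [
            ("S0", "case", "knee", 66.0, "female", 34.9, "no"),
            ("S1", "case", "hip", 67.4, "male", 31.1, "yes"),
            ("S2", "case", "knee", 60.0, "female", 33.0, "no"),
            ("S3", "control", "none", 56.4, "female", 29.5, "no"),
            ("S4", "control", "none", 58.0, "male", 28.0, "no"),
            ("S5", "control", "none", 55.0, "female", 30.0, "no"),
        ]
    )
    return g, s
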