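import numpy as np
import pytest

from fedcep.preprocess import EHRTable
from fedcep.synthetic import CohortSpec, default_cohort_spec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cohort():
    """200-record mixed-type cohort with 10% missingness."""
    return generate_cohort(default_cohort_spec(200, missing_rate=0.1, seed=11))


@pytest.fixture
def clean_cohort():
    """500-record separable cohort without missingness."""
    return generate_cohort(default_cohort_spec(500, seed=3, label_scale=6.0))


@pytest.fixture
def tiny_spec():
    return CohortSpec(
        n_records=50,
        numeric_features=[("a", 0.0, 1.0), ("b", 5.0, 2.0)],
        categorical_features=[("g", ("x", "y"), (0.4, 0.6))],
        coefficients=[1.0, -1.0],
        seed=5,
    )


@pytest.fixture
def raw_table(small_cohort):
    return EHRTable(small_cohort)
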