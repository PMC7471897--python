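import numpy as np
import pytest

from ssnod.cohort import CohortConfig, generate_mechanistic_cohort
from ssnod.pipeline import build_cohort_table


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition mechanistic cohort (31/64/132 nodules), fixed seed."""
    return generate_mechanistic_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    """Feature table with FPC scores for the default mechanistic cohort."""
    table, model = build_cohort_table(default_cohort)
    return table, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
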