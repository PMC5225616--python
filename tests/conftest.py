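import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from qalypy import default_spec, generate_cohort

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_default_cohort():
    """One default-spec cohort, shared read-only across tests."""
    return generate_cohort(default_spec(n=4000, seed=20110))


@pytest.fixture
def mixed_records():
    """Five records with mixed utilities, weights and censoring."""
    return pd.DataFrame({
        "time": [1.0, 2.0, 2.0, 3.5, 4.0],
        "event": [1, 1, 0, 1, 0],
        "weight": [1.0, 2.0, 1.5, 0.5, 3.0],
        "utility": [0.9, 0.6, 0.8, 0.4, 0.95],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20110)
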