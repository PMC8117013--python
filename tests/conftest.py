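import numpy as np
import pandas as pd
import pytest

from dendrobai.covariates import build_covariate_table
from dendrobai.synthetic import default_truth, generate_monthly_climate, simulate_dataset


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def dataset(truth):
    """One default synthetic study, shared read-only across tests."""
    return simulate_dataset(truth, seed=1)


@pytest.fixture(scope="session")
def covariates(dataset):
    """Covariate table over the 1950–2005 analysis span."""
    return dataset.covariates.loc[1950:2005]


@pytest.fixture(scope="session")
def climate(truth):
    return generate_monthly_climate(truth.climate, range(1950, 2006), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250928)
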