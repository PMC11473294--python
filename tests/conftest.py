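import numpy as np
import pytest

from ineqdecomp import DGPConfig, generate_cohort, load_fixture_tables, prepare_cohort


@pytest.fixture(scope="session")
def default_config():
    return DGPConfig()


@pytest.fixture(scope="session")
def cohort_df(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def prepared(cohort_df):
    return prepare_cohort(cohort_df)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixture_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
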