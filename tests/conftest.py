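import numpy as np
import pytest

from cllstrat.schema import load_reference_schema
from cllstrat.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def reference_schema():
    return load_reference_schema()


@pytest.fixture(scope="session")
def planted_cohort():
    """The default study conditions: 411 patients (243 u / 168 m), three
    u-IGHV and two m-IGHV planted subgroups, 5% feature flip noise."""
    return generate_cohort(default_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def u_matrix(planted_cohort):
    """features x patients matrix of the u-IGHV stratum."""
    pats = planted_cohort.stratum_patients("u")
    return planted_cohort.feature_matrix.values.loc[pats].T


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
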