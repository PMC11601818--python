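import numpy as np
import pandas as pd
import pytest

from ch4subtype import (
    SimulationConfig,
    fit_norming_model,
    generate_hc_cohort,
    generate_pdmci_cohort,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def hc_cohort(default_config):
    return generate_hc_cohort(default_config)


@pytest.fixture(scope="session")
def pdmci(default_config):
    return generate_pdmci_cohort(default_config)


@pytest.fixture(scope="session")
def norming_model(hc_cohort):
    return fit_norming_model(hc_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_visits():
    """One subject, MoCA drifting below the milestone cutoff at month 12."""
    return pd.DataFrame({
        "subject_id": ["s1"] * 3,
        "visit_month": [0.0, 6.0, 12.0],
        "moca": [25, 23, 20],
        "updrs_1_1": [0, 1, 1],
        "updrs_1_2": [0, 0, 0],
        "updrs_1_5": [0, 0, 0],
        "dementia_clinical": [False] * 3,
        "dementia_composite": [False] * 3,
    })
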