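import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from abscopal.parameters import default_parameters
from abscopal.radiation import default_dose_response_model
from abscopal.synthetic import design_from_paper, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_table():
    return default_parameters()


@pytest.fixture(scope="session")
def params(params_table):
    return params_table[0]


@pytest.fixture(scope="session")
def table(params_table):
    return params_table[1]


@pytest.fixture(scope="session")
def drm(table):
    return default_dose_response_model(table)


@pytest.fixture(scope="session")
def noiseless_dataset(params, table):
    """Full four-group design simulated at the calibrated parameters, no noise."""
    design = design_from_paper(noise_cv=0.0, seed=11)
    return generate(design, params, table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
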