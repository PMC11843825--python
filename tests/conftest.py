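import numpy as np
import pytest

from burndyn.chromophores import LayerModelConfig, load_chromophores
from burndyn.synthetic import CohortConfig, generate_cohort, reference_scenarios


@pytest.fixture(scope="session")
def lib():
    return load_chromophores()


@pytest.fixture(scope="session")
def model_cfg():
    return LayerModelConfig()


@pytest.fixture(scope="session")
def scenarios():
    return reference_scenarios()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (59 wounds, no cube rendering)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
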