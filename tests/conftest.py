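import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from mscgrowth import ModelParameters

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from mscgrowth.presets import EXPERIMENT_A, EXPERIMENT_B, experiment_b_hypoxia


@pytest.fixture(scope="session")
def expa_normoxia() -> ModelParameters:
    return EXPERIMENT_A["normoxia"]


@pytest.fixture(scope="session")
def expa_hypoxia() -> ModelParameters:
    return EXPERIMENT_A["hypoxia"]


@pytest.fixture(scope="session")
def expb_normoxia() -> ModelParameters:
    return EXPERIMENT_B["normoxia"]


@pytest.fixture(scope="session")
def expb_hypoxia() -> ModelParameters:
    return experiment_b_hypoxia(110.0)


@pytest.fixture(scope="session")
def all_conditions(expa_normoxia, expa_hypoxia, expb_normoxia, expb_hypoxia):
    return {
        "expA-normoxia": expa_normoxia,
        "expA-hypoxia": expa_hypoxia,
        "expB-normoxia": expb_normoxia,
        "expB-hypoxia": expb_hypoxia,
    }
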