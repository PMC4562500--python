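import numpy as np
import pytest

from pfevo.environment import Environment
from pfevo.fitness import FitnessParams, ExpressionModes
from pfevo.switching import SwitchingParams


@pytest.fixture(scope="session")
def params() -> FitnessParams:
    return FitnessParams()


@pytest.fixture(scope="session")
def switching() -> SwitchingParams:
    return SwitchingParams()


@pytest.fixture(scope="session")
def modes() -> ExpressionModes:
    return ExpressionModes()


@pytest.fixture(scope="session")
def envs() -> dict:
    return {lab: Environment.from_label(lab)
            for lab in ("D0Z0", "DiZ0", "D2Z0", "D0Z2", "DiZ2", "D2Z2")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150831)
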