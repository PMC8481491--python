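import numpy as np
import pytest

from biogeodiv.dec import AreaScheme, StratifiedModel


@pytest.fixture(scope="session")
def scheme3():
    return AreaScheme(("A", "B", "C"))


@pytest.fixture(scope="session")
def scheme4():
    return AreaScheme(("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def flat_model3(scheme3):
    return StratifiedModel.uniform(scheme3, 1000.0)


@pytest.fixture(scope="session")
def flat_model4(scheme4):
    return StratifiedModel.uniform(scheme4, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
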