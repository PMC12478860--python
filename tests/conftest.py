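import numpy as np
import pytest

from pdcondensate.forcefield import ForceFieldParams


@pytest.fixture(scope="session")
def ff() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
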