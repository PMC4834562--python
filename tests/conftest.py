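import numpy as np
import pytest

from opsinkit import synthgen
from opsinkit.kinetics import OpsinParams


@pytest.fixture(scope="session")
def chr2_6() -> OpsinParams:
    return synthgen.chr2_fixture(6)


@pytest.fixture(scope="session")
def chr2_4() -> OpsinParams:
    return synthgen.chr2_fixture(4)


@pytest.fixture(scope="session")
def chr2_3() -> OpsinParams:
    return synthgen.chr2_fixture(3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
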