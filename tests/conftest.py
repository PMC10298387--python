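import numpy as np
import pytest

from spinfold.analysis import ContactDefinition
from spinfold.targets import (
    derive_go_parameters,
    make_hairpin_target,
    make_helix_target,
)


@pytest.fixture(scope="session")
def helix20():
    return make_helix_target(20)


@pytest.fixture(scope="session")
def hairpin12():
    return make_hairpin_target(12)


@pytest.fixture(scope="session")
def go_helix20(helix20):
    return derive_go_parameters(helix20)


@pytest.fixture(scope="session")
def cdef():
    return ContactDefinition()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
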