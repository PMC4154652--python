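import numpy as np
import pytest

from isletcrit.lattice import build_cubic_lattice


@pytest.fixture(scope="session")
def spec11():
    return build_cubic_lattice(11)


@pytest.fixture(scope="session")
def spec2():
    return build_cubic_lattice(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
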