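import numpy as np
import pytest

from flpga import load_builtin_library, make_planted_space, make_quench_fixture


@pytest.fixture(scope="session")
def minilib():
    return load_builtin_library()


@pytest.fixture(scope="session")
def planted():
    return make_planted_space(seed=0)


@pytest.fixture(scope="session")
def quench_fixture():
    return make_quench_fixture(200, separation=0.5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
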