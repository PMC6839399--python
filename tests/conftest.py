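import numpy as np
import pytest

from crossmodal_rsa.conditions import build_condition_space
from crossmodal_rsa.simulate import generate_feature_norms


@pytest.fixture(scope="session")
def space():
    return build_condition_space()


@pytest.fixture(scope="session")
def norms(space):
    return generate_feature_norms(space, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
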