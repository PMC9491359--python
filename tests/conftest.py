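import numpy as np
import pytest

from fpvs.cluster import build_adjacency
from fpvs.simulate import make_layout
from fpvs.stimuli import load_default_inventory


@pytest.fixture(scope="session")
def layout160():
    return make_layout(160)


@pytest.fixture(scope="session")
def adjacency160(layout160):
    return build_adjacency(layout160)


@pytest.fixture(scope="session")
def adult_inventory():
    return load_default_inventory("adult")


@pytest.fixture(scope="session")
def child_inventory():
    return load_default_inventory("child")


@pytest.fixture()
def rng():
    return np.random.default_rng(20220907)
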