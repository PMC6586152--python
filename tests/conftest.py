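import numpy as np
import pytest

from attnlink import structures as st


@pytest.fixture(scope="session")
def s54():
    return st.load_structure("5_4")


@pytest.fixture(scope="session")
def shj():
    return st.load_structure("shj")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
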