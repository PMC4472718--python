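import numpy as np
import pytest

import oligoplex as ox


@pytest.fixture(scope="session")
def panel():
    return ox.load_default_panel()


@pytest.fixture(scope="session")
def apc_cfg():
    return ox.load_apc_config()


@pytest.fixture(scope="session")
def designed_apc(panel, apc_cfg):
    """One verified construct shared by the read-only tests."""
    return ox.design_apc(panel, apc_cfg["sizes"], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150618)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
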