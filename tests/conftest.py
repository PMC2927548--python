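import numpy as np
import pytest

from xenopass import simcohort as sim


@pytest.fixture(scope="session")
def apc_mcc():
    """Packaged two-genome scenario: driver/passenger pair adjacent in genome A,
    separated ~10.5 Mb in genome B by an inversion."""
    omap, events, roles = sim.apc_mcc_scenario(seed=0)
    return omap, events, roles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
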