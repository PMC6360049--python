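import numpy as np
import pytest

from hkemidif.phantom import PhantomConfig, TissueTACTable, make_frame_scheme, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """48x48 single-slice phantom with noiseless guidance (deterministic)."""
    cfg = PhantomConfig(grid_size=48, guidance_noise_sigma=0.0)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def default_scheme():
    return make_frame_scheme()


@pytest.fixture(scope="session")
def tac_table():
    return TissueTACTable.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
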