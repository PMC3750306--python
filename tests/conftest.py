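import numpy as np
import pytest

import bclgate as bg


@pytest.fixture(scope="session")
def params() -> bg.KineticParameters:
    return bg.default_parameters()


@pytest.fixture(scope="session")
def or_pools() -> bg.PoolConfiguration:
    return bg.POOL_PRESETS["OR"]


@pytest.fixture(scope="session")
def and_pools() -> bg.PoolConfiguration:
    return bg.POOL_PRESETS["AND"]


@pytest.fixture(scope="session")
def and_star_pools() -> bg.PoolConfiguration:
    return bg.POOL_PRESETS["AND_STAR"]


@pytest.fixture(scope="session")
def bax_bif(params) -> float:
    return bg.find_bifurcation(params).bax_bif


@pytest.fixture(scope="session")
def or_rest(params, or_pools) -> np.ndarray:
    """Resting (zero-input) steady state of the high-Bad (OR) cell."""
    return bg.bcl2_steady_state(bg.InputPoint(0.0, 0.0), or_pools, params)


@pytest.fixture(scope="session")
def and_rest(params, and_pools) -> np.ndarray:
    return bg.bcl2_steady_state(bg.InputPoint(0.0, 0.0), and_pools, params)
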