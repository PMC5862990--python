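import numpy as np
import pytest

from mmrtfluct import MMRTParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mall_params():
    """MalL-like activation parameters (large negative dCp, Topt ~320 K)."""
    return MMRTParams(dH_T0=50.0, dS_T0=-0.05, dCp=-11.6, T0=316.0)


@pytest.fixture
def ksi_params():
    """KSI-like activation parameters (mild curvature, Topt far above 320 K)."""
    return MMRTParams(dH_T0=30.0, dS_T0=-0.08, dCp=-0.86, T0=330.0)
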