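import numpy as np
import pytest

from curtainkit.units import CurtainGeometry
from curtainkit.synthetic_curtain import SimParams


@pytest.fixture
def geometry():
    return CurtainGeometry()


@pytest.fixture
def clean_params():
    """Noise-free single-run simulation parameters."""
    return SimParams(seed=2, n_molecules=1, p_release_per_event=0.0,
                     p_reversal=0.0, stall_rate=0.0, noise_sd_px=0.0,
                     lag_distribution="uniform", lag_scale_s=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
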