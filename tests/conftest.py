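import numpy as np
import pytest

from croplidar import SimConfig, build_field_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """One block, three doses: a 3-parcel field for fast end-to-end runs."""
    return build_field_layout(blocks=1, treatments=[0.0, 150.0, 300.0])


@pytest.fixture
def noiseless_config():
    """No range noise, no row texture, no outliers: the exact-recovery regime."""
    return SimConfig(noise_half_width=0.0, row_amplitude=0.0, seed=7)
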