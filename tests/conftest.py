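import numpy as np
import pytest

from gxedyn import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast, fully featured configuration for unit tests."""
    return SimulationConfig(
        n_snps=10,
        n_dyn=2,
        n_static=5,
        t_end=50.0,
        dt=0.1,
        record_every=1.0,
        seed=7,
    )
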