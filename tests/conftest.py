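import numpy as np
import pytest

from angiomet.config import default_config
from angiomet.lattice import Lattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return Lattice((8, 8, 8), 20.0)


@pytest.fixture
def tiny_config():
    """A small, fast scenario configuration (16^3 lattice, short burn-in)."""
    cfg = default_config()
    cfg.lattice.dims = (16, 16, 16)
    cfg.run.burn_in = 10.0
    cfg.run.end_time = 5.0
    cfg.run.initial_healthy_fraction = 0.25
    cfg.run.tumour_radius_sites = 1
    cfg.run.seed = 7
    return cfg
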