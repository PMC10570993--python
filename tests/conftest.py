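import numpy as np
import pytest

from npcsim.npc_assembly import SimulationConfig, assemble
from npcsim.reference_models import bands_from_ru, default_two_ring_ru, make_synthetic_ru


@pytest.fixture
def two_ring_bands():
    """Two-band (CR + NR) specs from the default synthetic reference unit."""
    return bands_from_ru(default_two_ring_ru())


@pytest.fixture
def two_ring_model(two_ring_bands):
    """Undeformed 8-fold assembly of the default two-ring unit."""
    return assemble(two_ring_bands, s=8)


@pytest.fixture
def three_ring_model():
    """CR/IR/NR model with a sandwiched band for interpolation tests."""
    ru = make_synthetic_ru(
        g=3,
        z_list=[25.0, 0.0, -25.0],
        r_list=[53.0, 40.0, 53.0],
        alpha_list=[0.0, 0.1, 0.0],
        subcomplex_list=["CR", "IR", "NR"],
    )
    return assemble(bands_from_ru(ru), s=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_config():
    return SimulationConfig(seed=7)
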