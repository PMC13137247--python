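import numpy as np
import pytest

from petfes.cg_polymer import ChainGeometry, TorsionPotential


@pytest.fixture(scope="session")
def geometry():
    return ChainGeometry()


@pytest.fixture(scope="session")
def amorphous_potential():
    """Gauche-favoring potential near the experimental amorphous gap."""
    return TorsionPotential(gt_gap=-4.09, barrier=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
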