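import numpy as np
import pytest

from avbmc.cluster_mc import MoveParams, ReservoirSpec
from avbmc.lattice import FccLattice

SPACING = 1.128  # FCC nearest-neighbor distance of the LJ solid at T = 0.6


@pytest.fixture
def lattice():
    return FccLattice(spacing=SPACING)


@pytest.fixture
def reservoir():
    return ReservoirSpec(T=0.6, n_v=1.0)


@pytest.fixture
def solid_params():
    return MoveParams(r=0.5)


@pytest.fixture
def liquid_params():
    return MoveParams(R=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def synthetic_histogram(n_min, beta_dg, beta_eta, n_total, rng, n_blocks=5):
    """Multinomial size samples from known free energies under a known bias."""
    from avbmc.umbrella import SizeHistogram
    w = np.exp(-(np.asarray(beta_dg) + np.asarray(beta_eta)))
    p = w / w.sum()
    per_block = n_total // n_blocks
    blocks = np.stack([rng.multinomial(per_block, p) for _ in range(n_blocks)])
    return SizeHistogram(n_min, blocks.astype(float))
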