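import numpy as np
import pytest

from kneeland import fibril as fb
from kneeland import forcefield as ffmod


@pytest.fixture(scope="session")
def ff():
    return ffmod.ForceFieldParams()


def desk_fibril(beta: float, seed: int = 0) -> fb.Fibril:
    """Reduced tensile fixture: 7 lattice sites, two 16.8-nm molecules in
    series per site, junctions staggered, axial gap beyond the LJ cutoff so
    the load crosses junctions through crosslinks and lateral shear."""
    return fb.build_fibril(diameter_nm=5.2, beta=beta,
                           molecule_length_nm=16.8, bead_spacing_nm=1.4,
                           n_axial=2, stagger_nm=4.2, axial_gap_nm=4.2,
                           seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
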