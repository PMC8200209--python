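import numpy as np
import pytest

from carbsorb.chemstruct import AtomRecord, MoleculeGeometry, SurfaceSlab
from carbsorb.surfaces import (
    SlabSpec,
    build_amorphous_slab,
    enumerate_mchm_conformers,
)


@pytest.fixture(scope="session")
def small_slab() -> SurfaceSlab:
    """A 2×2×1.5 nm amorphous slab — big enough for a 6 Å cutoff, small
    enough to keep pose minimization fast."""
    return build_amorphous_slab(SlabSpec(2.0, 2.0, 1.5, 2.0, 0.3, seed=3))


@pytest.fixture(scope="session")
def paper_scale_slab() -> SurfaceSlab:
    """The full 5×5×3 nm, 2.0 g/cc slab (thousands of atoms)."""
    return build_amorphous_slab(SlabSpec(5.0, 5.0, 3.0, 2.0, 0.3, seed=7))


@pytest.fixture(scope="session")
def cis_conformers():
    return enumerate_mchm_conformers("cis", 120.0)


@pytest.fixture(scope="session")
def trans_conformers():
    return enumerate_mchm_conformers("trans", 120.0)


@pytest.fixture
def water_like() -> MoleculeGeometry:
    return MoleculeGeometry(
        [
            AtomRecord("O", [0.0, 0.0, 0.117]),
            AtomRecord("H", [0.0, 0.757, -0.469]),
            AtomRecord("H", [0.0, -0.757, -0.469]),
        ],
        name="water-like toy",
    )


def single_atom_surface(element="C"):
    geom = MoleculeGeometry([AtomRecord(element, [0.0, 0.0, 0.0])])
    return geom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
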