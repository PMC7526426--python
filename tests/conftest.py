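import numpy as np
import pytest
from hypothesis import settings

from tracealign import make_backbone, make_family, make_helix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from tracealign.synthetic import random_rotation


PDB_THREE_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  MET A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def backbone40():
    return make_backbone(40, seed=11)


@pytest.fixture(scope="session")
def helix20():
    return make_helix(20)


@pytest.fixture(scope="session")
def family_small():
    """Five-member noisy family with an indel each: exercises gap handling."""
    return make_family(n=5, L=40, noise_sigma=0.4, n_indels=1, seed=21)


@pytest.fixture(scope="session")
def family_rigid():
    """Noise-free family: every member is a rigid copy of the ancestor."""
    return make_family(n=4, L=30, noise_sigma=0.0, n_indels=0, seed=33)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rigid_copy(structure, seed: int):
    """Apply a random proper rigid motion; returns a same-id copy."""
    from tracealign.structure_io import ProteinStructure

    gen = np.random.default_rng(seed)
    R = random_rotation(gen)
    t = gen.uniform(-15, 15, size=3)
    return ProteinStructure(
        id=structure.id,
        residue_names=list(structure.residue_names),
        residue_numbers=list(structure.residue_numbers),
        coords=structure.coords @ R.T + t,
    )
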