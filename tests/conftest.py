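"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest
import biotite.structure as struc

from agekit.structures import Structure
from agekit.synthetic import (
    PlantedComplexSpec,
    make_extended_tripeptide,
    make_planted_complex,
    make_polypeptide,
)


@pytest.fixture(scope="session")
def planted():
    """Standard planted complex: 3 salt bridges, 2 H-bonds, 1 pi-stack,
    2 steric decoys."""
    spec = PlantedComplexSpec(
        n_salt_bridges=3, n_hbonds=2, n_pipi=1, n_steric=2, seed=7
    )
    return make_planted_complex(spec)


@pytest.fixture(scope="session")
def lys_tripeptide():
    return make_extended_tripeptide("K")


def _two_chain_complex(v_start, albumin_seq="KAKEKAKEKAKEKAKEKAKEKAKEKAKEKA"):
    """Albumin-like helix (chain A) plus a V-domain-like helix (chain B,
    receptor numbering from residue 23)."""
    alb = make_polypeptide(albumin_seq, "A", (0.0, 0.0, 0.0))
    v = make_polypeptide("A" * 97, "B", v_start, first_res_id=23)
    return Structure(struc.stack([alb + v]), source="synthetic-complex")


@pytest.fixture(scope="session")
def ghsa_v_complex():
    return _two_chain_complex((0.0, 25.0, 0.0))


@pytest.fixture(scope="session")
def ghsa_v_complex_far():
    """Same albumin, V-domain on the opposite face."""
    return _two_chain_complex((0.0, -45.0, 0.0))


@pytest.fixture(scope="session")
def vc1c2_reference():
    """Full ectodomain stand-in: one chain spanning receptor residues
    23..325, same ideal helix geometry as the complex fixtures so the
    V-region superposes exactly."""
    arr = make_polypeptide("A" * 303, "R", (0.0, 25.0, 0.0), first_res_id=23)
    return Structure(struc.stack([arr]), source="synthetic-ref")


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=20.0, size=3)
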