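import warnings
from pathlib import Path

import numpy as np
import pytest

from fbrefine.fixtures import FixtureSpec, build_polypeptide, perturb
from fbrefine.restraints import build_restraints
from fbrefine.structure import find_hydrogen_groups

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def helix10():
    """10-residue ideal poly-alanine α-helix with hydrogens."""
    return build_polypeptide(FixtureSpec(n_residues=10, conformation="helix"))


@pytest.fixture(scope="session")
def helix_groups(helix10):
    return find_hydrogen_groups(helix10)


@pytest.fixture(scope="session")
def rset_shortest(helix10):
    return build_restraints(helix10, method="shortest", cutoff=7.0)


@pytest.fixture(scope="session")
def rset_r6(helix10):
    return build_restraints(helix10, method="r6", cutoff=7.0)


@pytest.fixture(scope="session")
def perturbed_helix(helix10):
    return perturb(helix10, 0.8, 7)


@pytest.fixture
def tripeptide_path():
    return DATA_DIR / "tripeptide.pdb"


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*r_min clamped.*")
        warnings.filterwarnings("ignore", message=".*d < w/2.*")
        yield


def ca_coords(structure) -> np.ndarray:
    return np.array([a.position for a in structure.atoms if a.name == "CA"])
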