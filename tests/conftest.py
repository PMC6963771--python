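import numpy as np
import pytest

from ensembleproj.structures import AtomKey, Structure


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       1.000   2.000   0.000  1.00  0.00           C
ATOM      4  CB  GLY A   2       9.000   9.000   9.000  1.00  0.00           C
ATOM      5  CA  SER A   3       1.000   2.000   3.500  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       0.000   3.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       0.000   0.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def make_structure(entry_id, coords, chain="A"):
    coords = np.asarray(coords, dtype=float)
    atoms = {AtomKey(chain, i + 1, ""): coords[i] for i in range(len(coords))}
    return Structure(entry_id, atoms)


@pytest.fixture
def toy_coords():
    rng = np.random.default_rng(7)
    return rng.normal(scale=4.0, size=(12, 3))


@pytest.fixture
def toy_structure(toy_coords):
    return make_structure("toy", toy_coords)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return rot, t
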