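"""Shared fixtures: synthetic structures with known ground truth.

Everything is generated at test time; the quartet-placement tuning is
cached per process, so session-scoped fixtures amortize the expensive
first build.
"""

from __future__ import annotations

import numpy as np
import pytest

from quadgeom.quartets import build_core, detect_quartets
from quadgeom.synthetic import QuadruplexSpec, build_bdna_duplex, build_quadruplex


@pytest.fixture(scope="session")
def parallel_spec() -> QuadruplexSpec:
    return QuadruplexSpec()  # 3 layers, 30 deg twist, 3.3 A rise, loops "out"


@pytest.fixture(scope="session")
def parallel_quadruplex(parallel_spec):
    return build_quadruplex(parallel_spec)


@pytest.fixture(scope="session")
def parallel_core(parallel_quadruplex):
    return build_core(detect_quartets(parallel_quadruplex))


@pytest.fixture(scope="session")
def bdna_duplex():
    return build_bdna_duplex()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140901)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def apply_rigid(structure, rotation, translation):
    """Return a rigid-motion copy of a Structure."""
    from quadgeom.synthetic import copy_structure

    out = copy_structure(structure)
    for res in out.residues():
        for atom in res.atoms:
            atom.position = rotation @ atom.position + translation
    return out


MINIMAL_PDB = """\
CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1           1
ATOM      1  O5' DG  A   1       1.000   2.000   3.000  1.00 10.00           O
ATOM      2  C5' DG  A   1       2.000   2.500   3.000  1.00 12.00           C
ATOM      3  C1' DG  A   1       3.100   2.500   3.400  1.00 14.00           C
ATOM      4  O5' DA  A   2       4.000   5.000   6.000  1.00 20.00           O
ATOM      5  C5' DA  A   2       5.000   5.500   6.000  1.00 22.00           C
ATOM      6  O5' DT  B   1       8.000   8.000   8.000  1.00 30.00           O
ATOM      7  C5' DT  B   1       9.000   8.500   8.000  1.00 32.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  O5'ADG  A   1       1.000   2.000   3.000  0.40 10.00           O
ATOM      2  O5'BDG  A   1       1.500   2.000   3.000  0.60 11.00           O
ATOM      3  C5'ADG  A   1       2.000   2.500   3.000  0.50 12.00           C
ATOM      4  C5'BDG  A   1       2.500   2.500   3.000  0.50 13.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
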