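import numpy as np
import pytest

import ploopflex as pf


@pytest.fixture
def helix_spec():
    """10-residue poly-Ala at canonical alpha-helix dihedrals."""
    return pf.PeptideSpec.uniform("AAAAAAAAAA", phi=-57.0, psi=-47.0)


@pytest.fixture
def helix(helix_spec):
    return pf.build_peptide(helix_spec)


@pytest.fixture
def motif_peptide():
    """The HCMGGLGR phosphatase signature motif as a toy loop."""
    return pf.build_peptide(pf.PeptideSpec.uniform("HCMGGLGR", phi=-70.0, psi=-30.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def wrap_diff(a: float, b: float) -> float:
    """Angular distance in degrees, respecting the +/-180 wrap."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def coords_of(structure) -> np.ndarray:
    return np.array([a.coords for a in structure.all_atoms()])


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00 10.00"
    "           C\n"
    "END\n"
)
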