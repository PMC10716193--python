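import numpy as np
import pytest

from sqmbd.fixtures import FixtureSpec, dimer_system, generate
from sqmbd.pipeline import run_mbd

PDB_TEXT = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
TER
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00  0.00           H
ENDMDL
MODEL        2
ATOM      1  O   HOH A   1       9.000   9.000   9.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       9.957   9.000   9.000  1.00  0.00           H
ATOM      3  H2  HOH A   1       8.760   9.927   9.000  1.00  0.00           H
ENDMDL
END
"""


@pytest.fixture(scope="session")
def dipeptide_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "dipeptide.pdb"
    path.write_text(PDB_TEXT)
    return path


@pytest.fixture(scope="session")
def water_two_models_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "water2models.pdb"
    path.write_text(PDB_TWO_MODELS)
    return path


@pytest.fixture(scope="session")
def carbon_dimer():
    """Homonuclear carbon dimer at 5 Bohr with eta=0.9 (moderate coupling)."""
    return dimer_system(5.0, element="C", eta=0.9)


@pytest.fixture(scope="session")
def carbon_dimer_result(carbon_dimer):
    system, _ = carbon_dimer
    return run_mbd(system, screen=False)


@pytest.fixture(scope="session")
def cluster_result():
    """Screened pipeline result on a seeded 8-atom random cluster."""
    system, _ = generate(FixtureSpec(n_atoms=8, seed=3))
    return run_mbd(system)


@pytest.fixture(scope="session")
def two_blob():
    system, part = generate(FixtureSpec(n_atoms=10, geometry="two_blob", seed=7))
    return system, part, run_mbd(system)


def uncoupled_modes(n_atoms=2, omega=0.5):
    """Modes object for n uncoupled identical QDOs (identity modal matrix)."""
    from sqmbd.hamiltonian import MBDModes

    w = np.full(n_atoms, omega)
    return MBDModes(
        o=np.eye(3 * n_atoms),
        omega_tilde=np.repeat(w, 3),
        omega=w,
        e_mbd=0.0,
    )
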