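import numpy as np
import pytest

from fragkit import synthetic as syn
from fragkit import thermo
from fragkit.structures import parse_structure

# 3-residue hand-written fragment of a PDB file (read by eye in tests)
THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.576   5.577  -4.175  1.00  0.00           C
END
"""


@pytest.fixture
def three_atom_model():
    return parse_structure(THREE_ATOM_PDB, identifier="hand3")


@pytest.fixture
def line_toy():
    """Ligand at origin, five single-atom residues at x = 1..5 A."""
    return syn.generate_toy_structure(
        syn.ToyStructureSpec(n_residues=5, geometry="line", spacing=1.0)
    )


@pytest.fixture
def helix_toy():
    return syn.generate_toy_structure(
        syn.ToyStructureSpec(n_residues=15, geometry="helix", seed=11)
    )


@pytest.fixture
def vp_itc_protocol():
    """17 x 16.4 uL injections into a 1.4 mL cell, 10 uM cell / 130 uM syringe."""
    return thermo.TitrationProtocol(
        cell_volume=1.4e-3,
        cell_conc=10e-6,
        syringe_conc=130e-6,
        injection_volumes=(16.4e-6,) * 17,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
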