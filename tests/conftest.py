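import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles module importable

from aliqa.matrices import load_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def gonnet160():
    return load_matrix("GONNET160")


@pytest.fixture
def write_fasta(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "aln.fasta") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.800   1.200   0.300  1.00  0.00           C
ATOM      4  CA  SER A   3       8.100   2.500   0.900  1.00  0.00           C
ATOM      5  CA  LEU A   4      11.300   4.100   1.400  1.00  0.00           C
ATOM      6  CA  LYS A   5      14.500   5.800   2.200  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       4.800   1.200   0.300  1.00  0.00           C
ATOM      4  CA  SER A   3       8.100   2.500   0.900  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
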