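"""Shared fixtures: tiny handwritten PDB text and geometric builders."""

from __future__ import annotations

import numpy as np
import pytest

from pocketvote.sitepredict import ContactParams
from pocketvote.structio import AtomRecord, LigandInstance, Residue, StructureModel

# Three ALA residues along x plus one ZN and one water; altloc B of the ZN
# has higher occupancy and must win.
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.400   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.800   1.400   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.300   0.000   0.000  1.00  0.00           C
ATOM      7  N   ALA A   3       7.600   1.400   0.000  1.00  0.00           N
ATOM      8  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      9  C   ALA A   3       9.100   0.000   0.000  1.00  0.00           C
TER      10      ALA A   3
HETATM   11 ZN  AZN  B   1       2.000   2.000   0.000  0.40 10.00          ZN
HETATM   12 ZN  BZN  B   1       2.500   2.500   0.000  0.60 10.00          ZN
HETATM   13  O   HOH B   2      20.000  20.000  20.000  1.00 10.00           O
END
"""

WATERS_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATERS_ONLY_PDB)
    return p


@pytest.fixture
def params():
    return ContactParams()


def point_residue(seq: int, xyz, name: str = "GLY",
                  element: str = "C") -> Residue:
    """A one-atom residue (its atom doubles as the C-alpha)."""
    atom = AtomRecord(serial=seq, name="CA", element=element,
                      coords=np.asarray(xyz, float), residue_name=name,
                      residue_seq=seq, chain_id="A")
    return Residue(seq=seq, name=name, atoms=[atom])


def point_ligand(lid: str, xyz, resname: str = "ZN", element: str = "ZN",
                 ltype: str = "I", source: str = "t") -> LigandInstance:
    atom = AtomRecord(serial=1, name=element, element=element,
                      coords=np.asarray(xyz, float), residue_name=resname,
                      residue_seq=901, chain_id="Z", is_hetero=True)
    return LigandInstance(ligand_id=lid, atoms=[atom], resname=resname,
                          source_template=source, ltype=ltype)


def line_model(n: int, spacing: float = 4.0) -> StructureModel:
    """Residues on a straight line, for distance-metric tests."""
    return StructureModel(
        id="line",
        residues=[point_residue(i + 1, (i * spacing, 0.0, 0.0))
                  for i in range(n)])
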