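"""Shared synthetic fixtures (all generated at test time; no data files)."""

import numpy as np
import pytest

from protfeat.fixtures import build_helix, build_peptide, build_sheet_pair
from protfeat.structure import Atom, StructureDomain


def make_atom(serial=1, name="CA", altloc="", resname="ALA", chain="A",
              resseq=1, icode="", x=0.0, y=0.0, z=0.0, occ=1.0, b=0.0,
              element="C", het=False, charge=None, radius=None):
    return Atom(serial=serial, name=name, altloc=altloc, residue_name=resname,
                chain_id=chain, residue_seq=resseq, insertion_code=icode,
                x=x, y=y, z=z, occupancy=occ, bfactor=b, element=element,
                is_hetero=het, charge=charge, radius=radius)


@pytest.fixture(scope="session")
def helix15():
    return build_helix(15)


@pytest.fixture(scope="session")
def sheet_pair():
    return build_sheet_pair(6)


@pytest.fixture(scope="session")
def small_peptide():
    """5-residue mixed-torsion peptide exercising several residue types."""
    torsions = [(-57.0, -47.0), (-139.0, 135.0), (-75.0, 145.0),
                (60.0, 40.0), (-100.0, 120.0)]
    return build_peptide("AKDFG", torsions, domain_id="mix5")


@pytest.fixture
def single_carbon():
    return StructureDomain(domain_id="c1", atoms=[make_atom()])


PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      12.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      13.685   7.161  -4.922  1.00  0.00           C
ENDMDL
"""

PDB_MESSY = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60  0.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.100  0.40  0.00           C
ATOM      4  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      5  N   GLY B   1       1.000   2.000   3.000  1.00  0.00           N
HETATM    6  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM    7  O   HOH A 102       6.000   5.000   5.000  1.00  0.00           O
HETATM    8  O   HOH A 103       7.000   5.000   5.000  1.00  0.00           O
HETATM    9 ZN    ZN A 201       2.000   2.000   2.000  1.00  0.00          ZN
"""

# Legacy record without element columns: element must be inferred.
PDB_NO_ELEMENT = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00
HETATM    3 CA    CA A 201       2.000   2.000   2.000  1.00  0.00          CA
"""


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
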