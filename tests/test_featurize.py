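"""Feature calculators and the assembled feature table."""

import math

import numpy as np
import pandas as pd
import pytest

from protfeat import calculators as calc
from protfeat.constants import (
    ATOM_TYPES, ELEMENTS, RESIDUES_21, SEQUENCE_AA,
    assign_autodock_type, autodock_flags, hydrophobicity, vdw_radius,
)
from protfeat.featurize import featurize_domain
from protfeat.fixtures import build_peptide, make_toy_msa
from protfeat.schema import default_schema
from protfeat.structure import StructureDomain

from conftest import make_atom


class TestVocabularies:
    def test_one_hot_widths_and_single_one(self):
        assert len(calc.one_hot("FE", ELEMENTS)) == 16
        assert len(calc.one_hot("GLY", RESIDUES_21)) == 21
        assert len(calc.one_hot("C", ATOM_TYPES)) == 23
        assert len(calc.one_hot("A", SEQUENCE_AA)) == 20
        for vec in (calc.one_hot("FE", ELEMENTS), calc.one_hot("GLY", RESIDUES_21)):
            assert vec.sum() == 1

    def test_unknowns_map_to_unk_slot(self):
        vec = calc.one_hot("XX", RESIDUES_21)
        assert vec[RESIDUES_21.index("Unk_residue")] == 1

    def test_sequence_vocab_has_no_unknown(self):
        with pytest.raises(ValueError, match="no unknown slot"):
            calc.one_hot("B", SEQUENCE_AA)


class TestAutodockTyping:
    @pytest.mark.parametrize("name,res,elem,expected", [
        ("CD1", "PHE", "C", "A"),     # aromatic ring carbon
        ("O", "ALA", "O", "OA"),      # carbonyl oxygen acceptor
        ("CA", "ALA", "C", "C"),      # aliphatic carbon
        ("N", "ALA", "N", "N"),
        ("ND1", "HIS", "N", "NA"),
        ("SD", "MET", "S", "SA"),
        ("ZN", "ZN", "ZN", "ZN"),
        ("H", "ALA", "H", "HD"),      # backbone amide H
        ("HB1", "ALA", "H", "H"),     # apolar H
        ("XX", "UNK", "", "Unk_atom"),
    ])
    def test_typing(self, name, res, elem, expected):
        assert assign_autodock_type(name, res, elem) == expected

    @pytest.mark.parametrize("atype,flag,value", [
        ("OA", "hbond_acceptor", True),
        ("OA", "hbond_donor", False),
        ("ZN", "metal", True),
        ("HD", "hbond_donor", True),
        ("HD", "hbond_acceptor", False),
        ("A", "aromatic_atom", True),
        ("A", "hydrophobic_atom", True),
        ("C", "hydrophobic_atom", True),
        ("N", "hbond_acceptor", False),
    ])
    def test_flags(self, atype, flag, value):
        assert autodock_flags(atype)[flag] is value


class TestScalars:
    def test_vdw_radii(self):
        assert vdw_radius("C") == pytest.approx(1.70)
        assert vdw_radius("H") == pytest.approx(1.20)
        assert vdw_radius("XX") == pytest.approx(1.70)

    def test_hydrophobicity_values(self):
        assert hydrophobicity("ILE", "kd") == pytest.approx(4.5)
        assert hydrophobicity("ARG", "kd") == pytest.approx(-4.5)
        assert hydrophobicity("UNK", "kd") == 0.0
        assert hydrophobicity("UNK", "octanol") == 0.0
        with pytest.raises(ValueError, match="unknown hydrophobicity scale"):
            hydrophobicity("ALA", "bogus")


class TestCharges:
    def test_lysine_net_charge(self):
        pep = build_peptide("AKA", [(-57, -47)] * 3)
        charges = calc.partial_charges(pep)
        residues = pep.residues
        lys = charges[residues[1].atom_indices].sum()
        assert lys == pytest.approx(0.0)  # backbone-only fixture: no NZ atom
        dom = StructureDomain(atoms=[
            make_atom(name="NZ", resname="LYS", element="N"),
            make_atom(serial=2, name="CE", resname="LYS", element="C", x=1.5),
        ])
        # side chain alone: +1 from NZ (no backbone N present to pick up the
        # N-terminal charge)
        assert calc.partial_charges(dom).sum() == pytest.approx(1.0)

    def test_neutral_interior_alanine(self):
        pep = build_peptide("AAA", [(-57, -47)] * 3)
        charges = calc.partial_charges(pep)
        interior = pep.residues[1].atom_indices
        assert np.all(charges[interior] == 0.0)

    def test_pqr_passthrough_and_error(self):
        dom = StructureDomain(atoms=[make_atom(charge=-0.25, radius=1.5)])
        assert calc.partial_charges(dom, "pqr-file")[0] == pytest.approx(-0.25)
        dom2 = StructureDomain(atoms=[make_atom()])
        with pytest.raises(ValueError, match="no charge"):
            calc.partial_charges(dom2, "pqr-file")


class TestPotential:
    def test_zero_charges_zero_potential(self, small_peptide):
        q = np.zeros(len(small_peptide.atoms))
        assert np.all(calc.electrostatic_potential(small_peptide, q) == 0.0)

    def test_closed_form_pair(self):
        dom = StructureDomain(atoms=[
            make_atom(), make_atom(serial=2, x=2.0, resseq=2)])
        phi = calc.electrostatic_potential(dom, np.array([1.0, 1.0]))
        # 332.0636 * q / (eps(r) * r) with eps = 4r = 8 at r = 2
        assert phi == pytest.approx([332.0636 / 16.0] * 2)

    def test_negative_charge_gives_negative_potential(self):
        dom = StructureDomain(atoms=[
            make_atom(), make_atom(serial=2, x=3.0, resseq=2)])
        phi = calc.electrostatic_potential(dom, np.array([0.0, -1.0]))
        assert phi[0] < 0


class TestConcavity:
    def test_isolated_atom_capped(self, single_carbon):
        assert calc.concavity_cx(single_carbon)[0] == pytest.approx(15.0)

    def test_dense_ball_is_concave(self, rng):
        # ~sphere-filling lattice of atoms within 10 A of the center
        pts = [p for p in np.mgrid[-10:11:2, -10:11:2, -10:11:2].reshape(3, -1).T
               if np.linalg.norm(p) <= 10.0]
        atoms = [make_atom(serial=i + 1, x=float(p[0]), y=float(p[1]),
                           z=float(p[2]), resseq=i + 1) for i, p in enumerate(pts)]
        dom = StructureDomain(atoms=atoms)
        center = int(np.argmin([np.linalg.norm(p) for p in pts]))
        cx = calc.concavity_cx(dom)
        assert cx[center] < 2.0  # below the is_concave threshold

    def test_monotone_in_neighbor_count(self):
        values = []
        for n in (1, 3, 6, 10):
            atoms = [make_atom(serial=i + 1, x=2.0 * i, resseq=i + 1)
                     for i in range(n)]
            values.append(calc.concavity_cx(StructureDomain(atoms=atoms))[0])
        assert values == sorted(values, reverse=True)


class TestSasa:
    def test_isolated_atom_analytic(self, single_carbon):
        asa, _ = calc.sasa_shrake_rupley(single_carbon)
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2
        assert asa[0] == pytest.approx(analytic, rel=0.005)

    def test_distant_atoms_unoccluded(self):
        dom = StructureDomain(atoms=[
            make_atom(), make_atom(serial=2, x=10.0, resseq=2)])
        asa, _ = calc.sasa_shrake_rupley(dom)
        analytic = 4 * math.pi * 3.1 ** 2
        assert asa == pytest.approx([analytic, analytic], rel=1e-9)

    def test_overlapping_atoms_match_dense_oracle(self):
        dom = StructureDomain(atoms=[
            make_atom(), make_atom(serial=2, x=2.0, resseq=2)])
        asa, _ = calc.sasa_shrake_rupley(dom)
        oracle, _ = calc.sasa_shrake_rupley(dom, n_points=20000)
        assert asa.sum() < 2 * 4 * math.pi * 3.1 ** 2
        assert asa.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_buried_residue_rasa_low(self, helix15):
        _, rasa = calc.sasa_shrake_rupley(helix15)
        assert np.all(rasa >= 0.0) and np.all(rasa <= 1.0)


class TestEntropy:
    def test_conserved_and_uniform_columns(self):
        dom = StructureDomain(atoms=[
            make_atom(resseq=1), make_atom(serial=2, resseq=2, x=3.0)])
        rows = ["AC"] + ["A" + aa for aa in "ACDEFGHIKLMNPQRSTVWY" * 2]
        msa = "".join(f">s{i}\n{r}\n" for i, r in enumerate(rows[:21]))
        ent = calc.sequence_entropy(msa, dom)
        assert ent[0] == pytest.approx(0.0)
        # column 2 has each of 20 residues once plus an extra C
        assert ent[1] > 0.95

    def test_two_state_column_closed_form(self):
        dom = StructureDomain(atoms=[make_atom()])
        msa = ">a\nA\n>b\nA\n>c\nV\n>d\nV\n"
        ent = calc.sequence_entropy(msa, dom)
        assert ent[0] == pytest.approx(math.log(2) / math.log(20))

    def test_length_mismatch_raises(self):
        dom = StructureDomain(atoms=[make_atom()])
        with pytest.raises(ValueError, match="does not match"):
            calc.sequence_entropy(">a\nAC\n", dom)

    def test_msa_fixture_entropy(self, small_peptide):
        msa = make_toy_msa(5, [0, 2], n_rows=200, seed=1,
                           first_row=small_peptide.sequence())
        ent = calc.sequence_entropy(msa, small_peptide)
        assert ent[0] == pytest.approx(0.0)
        assert ent[2] == pytest.approx(0.0)
        assert np.all(ent[[1, 3, 4]] > 0.8)


class TestFeatureTable:
    def test_column_counts_match_schema(self, small_peptide):
        schema = default_schema()
        table = featurize_domain(small_peptide)
        assert list(table.atoms.columns) == schema.atom_columns()
        assert len(table.residues.columns) == len(schema.residue_columns())

    def test_one_hot_blocks_sum_to_one(self, small_peptide):
        table = featurize_domain(small_peptide)
        schema = default_schema()
        for group in ("atom_type_onehot", "element_onehot"):
            cols = [e.name for e in schema.group(group)]
            assert np.all(table.atoms[cols].sum(axis=1) == 1)
        res_cols = [e.name for e in schema.group("residue_onehot")]
        assert np.all(table.residues[res_cols].sum(axis=1) == 1)

    def test_residue_features_map_down(self, small_peptide):
        table = featurize_domain(small_peptide)
        res_of_atom = np.repeat(
            np.arange(len(small_peptide.residues)),
            [len(r.atom_indices) for r in small_peptide.residues])
        mapped = table.residues["hydrophobicity"].to_numpy()[res_of_atom]
        assert np.array_equal(table.atoms["hydrophobicity"].to_numpy(), mapped)

    def test_residue_charge_is_sum_of_atoms(self, small_peptide):
        table = featurize_domain(small_peptide)
        for r, res in enumerate(small_peptide.residues):
            expected = table.atoms["charge"].iloc[res.atom_indices].sum()
            assert table.residues["charge"].iloc[r] == pytest.approx(expected)

    def test_sin_cos_identity_where_defined(self, small_peptide):
        table = featurize_domain(small_peptide)
        res = table.residues
        defined = res["phi_defined"] == 1
        norm = res.loc[defined, "phi_sin"] ** 2 + res.loc[defined, "phi_cos"] ** 2
        assert np.allclose(norm, 1.0)

    def test_entropy_defaults_to_one_without_msa(self, small_peptide):
        table = featurize_domain(small_peptide)
        assert np.all(table.atoms["eppic_entropy"] == 1.0)
        assert np.all(table.residues["is_conserved"] == 0)
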