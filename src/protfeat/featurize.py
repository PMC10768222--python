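"""Assemble the full per-atom / per-residue feature table for a domain.

``featurize_domain`` runs every calculator, applies the schema's aggregation
rules (atom -> residue roll-ups, residue -> atom map-downs) and the Boolean
discretizations, and returns a :class:`FeatureTable` whose two data frames
carry exactly the schema's columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calculators as calc
from .aggregate import atoms_to_residues, discretize, map_down
from .constants import (
    ATOM_TYPES, ELEMENTS, RESIDUES_21,
    assign_autodock_type, autodock_flags, hydrophobicity, vdw_radius,
)
from .schema import FeatureSchema, default_schema
from .structure import StructureDomain


@dataclass
class FeatureTable:
    """Per-atom and per-residue feature matrices with named columns."""

    atoms: pd.DataFrame
    residues: pd.DataFrame
    ss8: list[str] = field(default_factory=list)

    @property
    def atom_columns(self) -> list[str]:
        return list(self.atoms.columns)

    @property
    def residue_columns(self) -> list[str]:
        return list(self.residues.columns)


def _residue_index_of_atoms(domain: StructureDomain) -> np.ndarray:
    idx = np.empty(len(domain.atoms), dtype=int)
    for r, res in enumerate(domain.residues):
        idx[res.atom_indices] = r
    return idx


def featurize_domain(
    domain: StructureDomain,
    providers: dict[str, str] | None = None,
    msa: str | None = None,
    schema: FeatureSchema | None = None,
) -> FeatureTable:
    """Compute every schema feature for a sanitized domain.

    ``providers`` currently selects the charge source ("builtin-formal",
    the default, or "pqr-file" when the domain was loaded from a PQR file).
    ``msa`` is aligned FASTA text for the sequence-entropy column; without
    it every position is scored maximally uncertain (1.0).
    """
    schema = schema or default_schema()
    providers = providers or {}
    residues = domain.residues
    n_atoms, n_res = len(domain.atoms), len(residues)
    if n_atoms == 0:
        raise ValueError("cannot featurize an empty domain")
    res_of_atom = _residue_index_of_atoms(domain)

    atom_cols: dict[str, np.ndarray] = {}

    # --- categorical one-hots ------------------------------------------
    atom_types = [
        assign_autodock_type(a.name, a.residue_name, a.element)
        for a in domain.atoms
    ]
    type_mat = np.stack([calc.one_hot(t, ATOM_TYPES) for t in atom_types])
    for k, name in enumerate(ATOM_TYPES):
        atom_cols[name] = type_mat[:, k]

    elem_mat = np.stack([
        calc.one_hot(a.element.upper(), ELEMENTS) for a in domain.atoms
    ])
    elem_names = [e if e.endswith("elem") else f"{e}_elem" for e in ELEMENTS]
    for k, name in enumerate(elem_names):
        atom_cols[name] = elem_mat[:, k]

    # --- continuous atom-level features --------------------------------
    atom_cols["vdw"] = np.array([
        a.radius if a.radius is not None else vdw_radius(a.element)
        for a in domain.atoms
    ])
    charge_provider = providers.get("charge", "builtin-formal")
    charges = calc.partial_charges(domain, provider=charge_provider)
    atom_cols["charge"] = charges
    atom_cols["electrostatic_potential"] = calc.electrostatic_potential(domain, charges)
    atom_cols["cx"] = calc.concavity_cx(domain)
    atom_asa, residue_rasa = calc.sasa_shrake_rupley(domain)
    atom_cols["atom_asa"] = atom_asa

    for flag_name in ("hydrophobic_atom", "aromatic_atom", "hbond_acceptor",
                      "hbond_donor", "metal"):
        atom_cols[flag_name] = np.array(
            [autodock_flags(t)[flag_name] for t in atom_types], dtype=np.uint8
        )

    # --- residue-level features -----------------------------------------
    res_cols: dict[str, np.ndarray] = {}
    res_names = [r.name.strip().upper() for r in residues]
    res_mat = np.stack([calc.one_hot(rn, RESIDUES_21) for rn in res_names])
    for k, name in enumerate(RESIDUES_21):
        res_cols[name] = res_mat[:, k]

    res_cols["hydrophobicity"] = np.array([hydrophobicity(rn, "kd") for rn in res_names])
    res_cols["biological_hydrophobicity"] = np.array(
        [hydrophobicity(rn, "biological") for rn in res_names])
    res_cols["octanol_hydrophobicity"] = np.array(
        [hydrophobicity(rn, "octanol") for rn in res_names])
    res_cols["residue_rasa"] = residue_rasa

    for name, values in calc.torsions(domain).items():
        res_cols[name] = values

    ss8, ss3 = calc.secondary_structure(domain)
    for col in ("is_helix", "is_sheet", "Unk_SS"):
        res_cols[col] = np.array([s == col for s in ss3], dtype=np.uint8)
    for state, col in calc.SS8_COLUMNS.items():
        res_cols[col] = np.array([s == state for s in ss8], dtype=np.uint8)

    if msa is not None:
        res_cols["eppic_entropy"] = calc.sequence_entropy(msa, domain)
    else:
        res_cols["eppic_entropy"] = np.ones(n_res)

    residue_frame = pd.DataFrame(res_cols)
    atom_frame = pd.DataFrame(atom_cols)

    # atom -> residue aggregation (charge sum, potential sum, cx/vdw mean, ...)
    rolled = atoms_to_residues(atom_frame, res_of_atom, n_res, schema)
    residue_frame = pd.concat([residue_frame, rolled], axis=1)

    # residue -> atom map-down of residue-level features
    down_cols = [e.name for e in schema
                 if e.level == "residue" and e.residue_agg == "map_down"
                 and e.group != "boolean"]
    atom_frame = pd.concat(
        [atom_frame, map_down(residue_frame, res_of_atom, down_cols)], axis=1
    )

    # Boolean discretization at both levels, then map residue-level booleans
    # (is_hydrophobic, residue_buried, is_conserved) down onto atoms.
    residue_frame = pd.concat([residue_frame, discretize(residue_frame)], axis=1)
    atom_bools = discretize(atom_frame)
    atom_frame = pd.concat([atom_frame, atom_bools], axis=1)
    residue_only = [c for c in ("is_hydrophobic", "residue_buried", "is_conserved")
                    if c not in atom_frame.columns]
    if residue_only:
        atom_frame = pd.concat(
            [atom_frame, map_down(residue_frame, res_of_atom, residue_only)], axis=1
        )

    # Order columns per schema.
    atom_frame = atom_frame[[n for n in schema.names if n in atom_frame.columns]]
    res_order = [n for n in schema.names if n in residue_frame.columns]
    residue_frame = residue_frame[res_order]

    return FeatureTable(atoms=atom_frame, residues=residue_frame, ss8=ss8)
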