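"""Reference tables used across the feature calculators.

All tables are transcribed from standard published sources and are the single
authority inside this package: van der Waals radii (Bondi-style element
radii), three residue hydrophobicity scales (Kyte-Doolittle; the biological
translocon scale of Hessa et al.; the Wimley-White octanol scale),
theoretical Gly-X-Gly maximum accessible surface areas (Tien et al. 2013),
and the AutoDock-style atom-type vocabulary with per-residue typing rules.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# One-hot vocabularies
# ---------------------------------------------------------------------------

#: 23 AutoDock-style atom type names, in canonical order.
ATOM_TYPES: tuple[str, ...] = (
    "H", "HD", "HS", "C", "A", "N", "NA", "NS", "OA", "OS", "F", "MG", "P",
    "SA", "S", "CL", "CA", "MN", "FE", "ZN", "BR", "I", "Unk_atom",
)

#: 16 element names (15 known + unknown placeholder).
ELEMENTS: tuple[str, ...] = (
    "C", "N", "O", "S", "H", "F", "MG", "P", "CL", "CA", "MN", "FE", "ZN",
    "BR", "I", "Unk_elem",
)

#: 20 standard residues + unknown placeholder.
RESIDUES_21: tuple[str, ...] = (
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
    "Unk_residue",
)

#: 20 standard amino-acid letters for sequence one-hot encoding (no unknown
#: slot; unknown letters are an error at this level).
SEQUENCE_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

WATER_RESIDUES: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})

# ---------------------------------------------------------------------------
# van der Waals radii (Angstrom), element-keyed.  Bondi radii for the common
# organic elements; standard crystallographic values for the metals.  Unknown
# elements fall back to DEFAULT_VDW.
# ---------------------------------------------------------------------------

VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "CA": 2.31, "MN": 2.05, "FE": 2.04, "ZN": 1.39,
}
DEFAULT_VDW: float = 1.70


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom for an element symbol.

    Unknown elements get the carbon-like default of 1.70 A.
    """
    return VDW_RADII.get(element.upper().strip(), DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Hydrophobicity scales (residue-level)
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Biological (translocon) scale: apparent free energy of membrane insertion,
# kcal/mol (Hessa et al.).  Negative = favors insertion (hydrophobic).
BIOLOGICAL: dict[str, float] = {
    "ALA": 0.11, "ARG": 2.58, "ASN": 2.05, "ASP": 3.49, "CYS": -0.13,
    "GLN": 2.36, "GLU": 2.68, "GLY": 0.74, "HIS": 2.06, "ILE": -0.60,
    "LEU": -0.55, "LYS": 2.71, "MET": -0.10, "PHE": -0.32, "PRO": 2.23,
    "SER": 0.84, "THR": 0.52, "TRP": 0.30, "TYR": 0.68, "VAL": -0.31,
}

# Wimley-White octanol scale: water->octanol transfer free energy, kcal/mol.
OCTANOL: dict[str, float] = {
    "ALA": 0.50, "ARG": 1.81, "ASN": 0.85, "ASP": 3.64, "CYS": -0.02,
    "GLN": 0.77, "GLU": 3.63, "GLY": 1.15, "HIS": 2.33, "ILE": -1.12,
    "LEU": -1.25, "LYS": 2.80, "MET": -0.67, "PHE": -1.71, "PRO": 0.14,
    "SER": 0.46, "THR": 0.25, "TRP": -2.09, "TYR": -0.71, "VAL": -0.46,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kd": KYTE_DOOLITTLE,
    "biological": BIOLOGICAL,
    "octanol": OCTANOL,
}

# ---------------------------------------------------------------------------
# Theoretical maximum accessible surface areas (A^2) in a Gly-X-Gly
# tripeptide (Tien et al. 2013, "theoretical" column); reference for
# relative accessibility.
# ---------------------------------------------------------------------------

MAX_ASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ASA: float = 200.0

# ---------------------------------------------------------------------------
# AutoDock-style typing rules for standard residues
# ---------------------------------------------------------------------------

# Aromatic-ring carbons (type "A") per residue.
_AROMATIC_CARBONS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
}

# Nitrogen acceptors (type "NA"); all other protein nitrogens are donors
# carrying polar hydrogens and typed "N".  The HIS ND1 choice follows the
# common NE2-protonated tautomer convention.
_ACCEPTOR_NITROGENS: frozenset[tuple[str, str]] = frozenset({
    ("HIS", "ND1"),
})

# Polar hydrogens (bonded to N/O/S), typed "HD"; everything else "H".
_POLAR_HYDROGENS: dict[str, frozenset[str]] = {
    "*": frozenset({"H", "HN", "H1", "H2", "H3", "HXT"}),   # backbone amide / termini
    "ARG": frozenset({"HE", "HH11", "HH12", "HH21", "HH22"}),
    "ASN": frozenset({"HD21", "HD22"}),
    "GLN": frozenset({"HE21", "HE22"}),
    "HIS": frozenset({"HD1", "HE2"}),
    "LYS": frozenset({"HZ1", "HZ2", "HZ3"}),
    "SER": frozenset({"HG"}),
    "THR": frozenset({"HG1"}),
    "TRP": frozenset({"HE1"}),
    "TYR": frozenset({"HH"}),
    "CYS": frozenset({"HG"}),
}

_METAL_ELEMENTS: frozenset[str] = frozenset({"MG", "CA", "MN", "FE", "ZN"})
_HALOGEN_ELEMENTS: frozenset[str] = frozenset({"F", "CL", "BR", "I"})


def assign_autodock_type(atom_name: str, residue_name: str, element: str) -> str:
    """Map an atom to one of the 23 AutoDock-style atom type names.

    Deterministic in (residue_name, atom_name, element); anything that cannot
    be typed falls back to ``Unk_atom``.
    """
    name = atom_name.strip().upper()
    res = residue_name.strip().upper()
    elem = element.strip().upper()

    if elem in _METAL_ELEMENTS:
        return elem
    if elem in _HALOGEN_ELEMENTS:
        return elem
    if elem == "P":
        return "P"
    if elem == "S":
        # Protein sulfurs (MET SD, CYS SG) are weak acceptors.
        return "SA" if res in RESIDUES_21 else "S"
    if elem == "O":
        return "OA"
    if elem == "N":
        if (res, name) in _ACCEPTOR_NITROGENS:
            return "NA"
        return "N"
    if elem == "C":
        if name in _AROMATIC_CARBONS.get(res, frozenset()):
            return "A"
        return "C"
    if elem == "H":
        if name in _POLAR_HYDROGENS["*"] or name in _POLAR_HYDROGENS.get(res, frozenset()):
            return "HD"
        return "H"
    return "Unk_atom"


# Boolean flags derived from the AutoDock type.
AROMATIC_TYPES: frozenset[str] = frozenset({"A"})
ACCEPTOR_TYPES: frozenset[str] = frozenset({"NA", "NS", "OA", "OS", "SA"})
DONOR_TYPES: frozenset[str] = frozenset({"HD", "HS"})
METAL_TYPES: frozenset[str] = frozenset({"MG", "CA", "MN", "FE", "ZN"})
HYDROPHOBIC_TYPES: frozenset[str] = frozenset({"C", "A"})


def autodock_flags(atom_type: str) -> dict[str, bool]:
    """Table-driven Boolean annotations for an AutoDock atom type."""
    return {
        "hydrophobic_atom": atom_type in HYDROPHOBIC_TYPES,
        "aromatic_atom": atom_type in AROMATIC_TYPES,
        "hbond_acceptor": atom_type in ACCEPTOR_TYPES,
        "hbond_donor": atom_type in DONOR_TYPES,
        "metal": atom_type in METAL_TYPES,
    }


def hydrophobicity(residue_name: str, scale: str = "kd") -> float:
    """Residue hydrophobicity on a named scale (``kd``, ``biological``,
    ``octanol``).  Unknown residues score 0.0; unknown scale names raise."""
    try:
        table = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ValueError(
            f"unknown hydrophobicity scale {scale!r}; "
            f"choose from {sorted(HYDROPHOBICITY_SCALES)}"
        ) from None
    return table.get(residue_name.strip().upper(), 0.0)
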