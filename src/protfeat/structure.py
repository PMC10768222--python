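"""Parsing, sanitization and writing of protein domain structures.

Supports the fixed-column PDB v3.3 dialect (ATOM/HETATM/MODEL/ENDMDL) and the
whitespace- or column-delimited PQR dialect (per-atom partial charge and
radius in the last two fields).  Sanitization reduces a possibly messy
multi-model, multi-conformer file to the single, unambiguous structure the
feature calculators expect: first model, one chain, first alternate location,
hetero-atoms and waters removed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .constants import THREE_TO_ONE, WATER_RESIDUES


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


# Two-letter element symbols that legitimately appear in PDB atom names.
_TWO_LETTER_ELEMENTS = {
    "MG", "CL", "CA", "MN", "FE", "ZN", "BR", "NA", "SE", "CU", "NI", "CO",
    "CD", "HG", "AL", "SI",
}

_STANDARD_RESIDUES = set(THREE_TO_ONE)


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    is_hetero: bool = False
    charge: float | None = None
    radius: float | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def residue_key(self) -> "ResidueKey":
        return ResidueKey(self.chain_id, self.residue_seq, self.insertion_code)


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: totally ordered by (chain, number, icode)."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atom_indices: list[int] = field(default_factory=list)


@dataclass
class StructureDomain:
    """A protein domain: an ordered atom list plus its residue grouping."""

    domain_id: str = ""
    superfamily: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def residues(self) -> list[Residue]:
        """Residues in atom-file order, each owning its atom indices."""
        out: list[Residue] = []
        index: dict[ResidueKey, Residue] = {}
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key()
            res = index.get(key)
            if res is None:
                res = Residue(key, atom.residue_name)
                index[key] = res
                out.append(res)
            res.atom_indices.append(i)
        return out

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        if not self.atoms:
            return np.empty((0, 3), dtype=float)
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def set_coordinates(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {xyz.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        for atom, row in zip(self.atoms, xyz):
            atom.x, atom.y, atom.z = float(row[0]), float(row[1]), float(row[2])

    def sequence(self) -> str:
        """One-letter sequence (X for non-standard residues)."""
        return "".join(
            THREE_TO_ONE.get(res.name.strip().upper(), "X") for res in self.residues
        )

    def copy(self) -> "StructureDomain":
        return StructureDomain(
            domain_id=self.domain_id,
            superfamily=self.superfamily,
            atoms=[dataclasses.replace(a) for a in self.atoms],
        )


# ---------------------------------------------------------------------------
# Element inference
# ---------------------------------------------------------------------------

def infer_element(raw_name: str, residue_name: str, is_hetero: bool) -> str:
    """Guess the element from a 4-column PDB atom-name field.

    Standard amino-acid atoms use the first alphabetic character of the
    stripped name (so " CA " is carbon).  For hetero records a leading
    two-letter symbol such as "FE" or calcium "CA" is recognized when the
    name starts in the first column of the field.
    """
    stripped = raw_name.strip()
    if not stripped:
        return ""
    res = residue_name.strip().upper()
    # Hetero/non-standard: a name occupying column 1 of the 4-char field may
    # be a two-letter element.
    if res not in _STANDARD_RESIDUES:
        padded = raw_name.ljust(4)
        two = padded[:2].strip().upper()
        if padded[0] != " " and two in _TWO_LETTER_ELEMENTS:
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise StructureError(f"line {lineno}: malformed {what} field {text!r}") from None


def _parse_int(text: str, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise StructureError(f"line {lineno}: malformed {what} field {text!r}") from None


def parse_pdb(text: str, domain_id: str = "") -> list[StructureDomain]:
    """Parse PDB-format text into one StructureDomain per model.

    Fixed-column fields follow PDB v3.3; MODEL/ENDMDL delimit models, with a
    single implicit model when absent.  The element is read from columns
    77-78 and inferred from the atom name when blank.
    """
    models: list[StructureDomain] = []
    current = StructureDomain(domain_id=domain_id)
    saw_model_record = False
    saw_atom = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            if saw_model_record and current.atoms:
                models.append(current)
                current = StructureDomain(domain_id=domain_id)
            saw_model_record = True
            continue
        if record.startswith("ENDMDL"):
            if current.atoms:
                models.append(current)
            current = StructureDomain(domain_id=domain_id)
            continue
        if record not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise StructureError(
                f"line {lineno}: ATOM/HETATM record shorter than coordinate "
                f"columns ({len(line)} chars)"
            )
        saw_atom = True
        raw_name = line[12:16]
        residue_name = line[17:20].strip()
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = infer_element(raw_name, residue_name, record == "HETATM")
        occupancy = line[54:60].strip() if len(line) >= 60 else ""
        bfactor = line[60:66].strip() if len(line) >= 66 else ""
        atom = Atom(
            serial=_parse_int(line[6:11].strip(), lineno, "serial"),
            name=raw_name.strip(),
            altloc=line[16].strip(),
            residue_name=residue_name,
            chain_id=line[21].strip(),
            residue_seq=_parse_int(line[22:26].strip(), lineno, "residue number"),
            insertion_code=line[26].strip(),
            x=_parse_float(line[30:38].strip(), lineno, "x"),
            y=_parse_float(line[38:46].strip(), lineno, "y"),
            z=_parse_float(line[46:54].strip(), lineno, "z"),
            occupancy=float(occupancy) if occupancy else 1.0,
            bfactor=float(bfactor) if bfactor else 0.0,
            element=element,
            is_hetero=(record == "HETATM"),
        )
        current.atoms.append(atom)

    if current.atoms:
        models.append(current)
    if not saw_atom:
        raise StructureError("no ATOM/HETATM records found: empty structure")
    return models


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name alignment: one-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (element and name.upper().startswith(element.upper())
                             and len(element) == 2):
        return name.ljust(4)
    return (" " + name).ljust(4)


def write_pdb(domain: StructureDomain, allow_empty: bool = False) -> str:
    """Serialize a sanitized domain as fixed-column PDB v3.3 ATOM records."""
    if not domain.atoms and not allow_empty:
        raise StructureError("refusing to write a 0-atom domain (pass allow_empty=True)")
    lines = []
    for atom in domain.atoms:
        for v in (atom.x, atom.y, atom.z):
            if abs(v) >= 10000.0:
                raise StructureError(
                    f"coordinate {v} exceeds the fixed-column PDB format range"
                )
        record = "HETATM" if atom.is_hetero else "ATOM  "
        lines.append(
            f"{record}{atom.serial:>5d} {_format_atom_name(atom.name, atom.element)}"
            f"{atom.altloc or ' '}{atom.residue_name:>3s} {atom.chain_id or ' '}"
            f"{atom.residue_seq:>4d}{atom.insertion_code or ' '}   "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
            f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PQR parsing / writing
# ---------------------------------------------------------------------------

def parse_pqr(text: str, domain_id: str = "") -> StructureDomain:
    """Parse PQR text; charge and radius come from the last two fields.

    Handles both the chain-bearing and the chain-less whitespace dialects.
    """
    domain = StructureDomain(domain_id=domain_id)
    saw_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        # ATOM serial name resname [chain] resseq x y z charge radius
        if len(fields) == 11:
            (_, serial, name, resname, chain, resseq,
             x, y, z, charge, radius) = fields
        elif len(fields) == 10:
            _, serial, name, resname, resseq, x, y, z, charge, radius = fields
            chain = ""
        else:
            raise StructureError(
                f"line {lineno}: expected 10 or 11 whitespace-delimited PQR "
                f"fields, got {len(fields)}"
            )
        try:
            charge_f = float(charge)
            radius_f = float(radius)
        except ValueError:
            raise StructureError(
                f"line {lineno}: non-numeric charge/radius ({charge!r}, {radius!r})"
            ) from None
        saw_atom = True
        domain.atoms.append(Atom(
            serial=_parse_int(serial, lineno, "serial"),
            name=name,
            altloc="",
            residue_name=resname,
            chain_id=chain,
            residue_seq=_parse_int(resseq, lineno, "residue number"),
            insertion_code="",
            x=_parse_float(x, lineno, "x"),
            y=_parse_float(y, lineno, "y"),
            z=_parse_float(z, lineno, "z"),
            element=infer_element(name.rjust(4) if len(name) < 4 else name,
                                  resname, line.startswith("HETATM")),
            is_hetero=line.startswith("HETATM"),
            charge=charge_f,
            radius=radius_f,
        ))
    if not saw_atom:
        raise StructureError("no ATOM/HETATM records found in PQR input")
    return domain


def write_pqr(domain: StructureDomain) -> str:
    """Serialize a domain with charges and radii as whitespace-PQR."""
    lines = []
    for atom in domain.atoms:
        if atom.charge is None or atom.radius is None:
            raise StructureError(
                f"atom {atom.serial} {atom.name} lacks charge/radius; "
                "cannot write PQR"
            )
        record = "HETATM" if atom.is_hetero else "ATOM"
        chain = f" {atom.chain_id}" if atom.chain_id else ""
        lines.append(
            f"{record:<6s}{atom.serial:>5d} {atom.name:<4s} {atom.residue_name:>3s}"
            f"{chain} {atom.residue_seq:>4d} "
            f"{atom.x:10.4f} {atom.y:10.4f} {atom.z:10.4f} "
            f"{atom.charge:8.4f} {atom.radius:7.4f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sanitization
# ---------------------------------------------------------------------------

def sanitize(
    models: list[StructureDomain] | StructureDomain,
    chain: str,
    keep_het: bool = False,
) -> StructureDomain:
    """Reduce raw models to a clean single-conformer, single-chain domain.

    Keeps only the first model, the requested chain and the first-listed
    alternate location per (residue, atom name); clears the altloc field;
    drops HETATM records and waters unless ``keep_het``.  Idempotent.
    """
    if isinstance(models, StructureDomain):
        models = [models]
    if not models:
        raise StructureError("no models to sanitize")
    model = models[0]

    available = sorted({a.chain_id for a in model.atoms})
    if chain not in available:
        raise StructureError(
            f"chain {chain!r} not present; available chains: {available}"
        )

    out = StructureDomain(domain_id=model.domain_id, superfamily=model.superfamily)
    seen: set[tuple[ResidueKey, str]] = set()
    for atom in model.atoms:
        if atom.chain_id != chain:
            continue
        if atom.residue_name.strip().upper() in WATER_RESIDUES:
            continue
        if atom.is_hetero and not keep_het:
            continue
        slot = (atom.residue_key(), atom.name)
        if slot in seen:
            continue  # later-listed altloc conformer
        seen.add(slot)
        clean = dataclasses.replace(atom, altloc="")
        out.atoms.append(clean)
    return out


def to_fasta(domain: StructureDomain, width: int = 60) -> str:
    """FASTA export of the domain sequence."""
    seq = domain.sequence()
    header = f">{domain.domain_id or 'domain'}"
    body = "\n".join(seq[i:i + width] for i in range(0, len(seq), width))
    return f"{header}\n{body}\n"
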