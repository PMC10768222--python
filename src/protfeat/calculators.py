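"""Native biophysical feature calculators.

Each public function computes one feature family on a sanitized
:class:`~protfeat.structure.StructureDomain`:

* formal partial charges (or pass-through of PQR charges),
* a screened Coulomb electrostatic potential with distance-dependent
  dielectric,
* atomic concavity as the empty/occupied volume ratio in a fixed sphere,
* Shrake-Rupley solvent-accessible surface area (per atom) and relative
  residue accessibility against Gly-X-Gly reference maxima,
* backbone phi/psi torsions with sine/cosine embeddings,
* an 8-state secondary-structure assignment from Kabsch-Sander backbone
  hydrogen-bond energies, collapsed to the 3-state helix/sheet/loop scheme,
* normalized Shannon sequence entropy from a multiple sequence alignment.

External tools that compute the same quantities (Poisson-Boltzmann solvers,
reference SASA/DSSP codes) can be substituted through provider hooks at the
``featurize_domain`` level; the calculators here are self-contained.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .constants import SEQUENCE_AA, THREE_TO_ONE, MAX_ASA_GXG, DEFAULT_MAX_ASA, vdw_radius
from .structure import StructureDomain

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def one_hot(value: str, vocabulary: tuple[str, ...] | list[str]) -> np.ndarray:
    """Indicator vector over a vocabulary.

    Unknown values map to a trailing ``Unk``-style slot when the vocabulary
    has one; otherwise they raise (the 20-letter sequence vocabulary has no
    unknown slot by design).
    """
    vec = np.zeros(len(vocabulary), dtype=np.uint8)
    try:
        idx = list(vocabulary).index(value)
    except ValueError:
        unk = [i for i, v in enumerate(vocabulary) if v.startswith("Unk")]
        if not unk:
            raise ValueError(
                f"value {value!r} not in vocabulary and no unknown slot available"
            ) from None
        idx = unk[0]
    vec[idx] = 1
    return vec


# ---------------------------------------------------------------------------
# Partial charges
# ---------------------------------------------------------------------------

# Simplified formal charges at pH ~7, placed on the terminal heavy atoms of
# ionizable groups.  Histidine is treated as neutral.
_FORMAL_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
}


def partial_charges(domain: StructureDomain, provider: str = "builtin-formal") -> np.ndarray:
    """Per-atom charges in elementary units.

    ``pqr-file`` copies charges loaded from a PQR file; ``builtin-formal``
    assigns the simplified formal-charge table (ionizable side chains, the
    N-terminal amine +1, the C-terminal carboxylate -0.5 on O and OXT).
    """
    n = len(domain.atoms)
    if provider == "pqr-file":
        charges = np.empty(n, dtype=float)
        for i, atom in enumerate(domain.atoms):
            if atom.charge is None:
                raise ValueError(
                    f"atom {atom.serial} {atom.name} has no charge; "
                    "load a PQR file before using the pqr-file provider"
                )
            charges[i] = atom.charge
        return charges
    if provider != "builtin-formal":
        raise ValueError(f"unknown charge provider {provider!r}")

    charges = np.zeros(n, dtype=float)
    residues = domain.residues
    for i, atom in enumerate(domain.atoms):
        key = (atom.residue_name.strip().upper(), atom.name.strip().upper())
        charges[i] = _FORMAL_CHARGES.get(key, 0.0)
    if residues:
        first, last = residues[0], residues[-1]
        for i in first.atom_indices:
            if domain.atoms[i].name.strip().upper() == "N":
                charges[i] += 1.0
        has_oxt = any(
            domain.atoms[i].name.strip().upper() == "OXT" for i in last.atom_indices
        )
        for i in last.atom_indices:
            name = domain.atoms[i].name.strip().upper()
            if name == "OXT" or (name == "O" and has_oxt):
                charges[i] += -0.5
            elif name == "O" and not has_oxt:
                # carboxylate without an explicit OXT carries the full charge
                # split target on the lone oxygen
                charges[i] += -0.5
    return charges


# ---------------------------------------------------------------------------
# Electrostatic potential (screened Coulomb)
# ---------------------------------------------------------------------------

def electrostatic_potential(
    domain: StructureDomain,
    charges: np.ndarray,
    min_distance: float = 0.1,
) -> np.ndarray:
    """Potential at each atom from all other charges, kcal/(mol*e).

    Uses a distance-dependent dielectric eps(r) = 4r, i.e.
    ``phi_i = 332.0636 * sum_j q_j / (4 * r_ij^2)``.  Pairs closer than
    ``min_distance`` Angstrom are excluded with a warning.
    """
    xyz = domain.coordinates()
    n = len(xyz)
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (n,):
        raise ValueError("charges length does not match atom count")
    if n == 0:
        return np.zeros(0)
    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(r, np.inf)
    too_close = r < min_distance
    if too_close.any():
        warnings.warn(
            f"{int(too_close.sum()) // 2} atom pairs closer than "
            f"{min_distance} A excluded from the potential",
            stacklevel=2,
        )
        r[too_close] = np.inf
    with np.errstate(divide="ignore"):
        contrib = charges[None, :] / (4.0 * r ** 2)
    return COULOMB_CONSTANT * contrib.sum(axis=1)


# ---------------------------------------------------------------------------
# Concavity (empty/occupied volume ratio)
# ---------------------------------------------------------------------------

def concavity_cx(
    domain: StructureDomain,
    sphere_radius: float = 10.0,
    atom_volume: float = 20.1,
    cap: float = 15.0,
) -> np.ndarray:
    """Per-atom concavity index.

    For each atom, the interior volume is the count of atoms within
    ``sphere_radius`` (including itself) times ``atom_volume``; cx is the
    ratio of the remaining (empty) sphere volume to the interior volume,
    clipped to [0, cap].  Protruding atoms score high, buried/concave
    environments low.
    """
    xyz = domain.coordinates()
    if len(xyz) == 0:
        return np.zeros(0)
    tree = cKDTree(xyz)
    counts = np.array([len(tree.query_ball_point(p, sphere_radius)) for p in xyz])
    v_int = counts * atom_volume
    v_sphere = (4.0 / 3.0) * math.pi * sphere_radius ** 3
    v_ext = np.maximum(v_sphere - v_int, 0.0)
    return np.clip(v_ext / v_int, 0.0, cap)


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent accessibility
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _atom_radii(domain: StructureDomain) -> np.ndarray:
    return np.array([
        a.radius if a.radius is not None else vdw_radius(a.element)
        for a in domain.atoms
    ])


def sasa_shrake_rupley(
    domain: StructureDomain,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrake-Rupley accessible surface area.

    Returns ``(atom_asa, residue_rasa)``: per-atom ASA in A^2 (fraction of
    test points on the probe-expanded sphere not occluded by any neighbor's
    expanded sphere, times the sphere area) and per-residue relative ASA in
    [0, 1] against the Gly-X-Gly theoretical maxima.
    """
    xyz = domain.coordinates()
    n = len(xyz)
    if n == 0:
        return np.zeros(0), np.zeros(0)
    radii = _atom_radii(domain) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()

    atom_asa = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        atom_asa[i] = accessible.mean() * 4.0 * math.pi * radii[i] ** 2

    residues = domain.residues
    rasa = np.zeros(len(residues))
    for k, res in enumerate(residues):
        total = atom_asa[res.atom_indices].sum()
        ref = MAX_ASA_GXG.get(res.name.strip().upper(), DEFAULT_MAX_ASA)
        rasa[k] = min(total / ref, 1.0)
    return atom_asa, rasa


# ---------------------------------------------------------------------------
# Backbone torsions
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def _backbone_index(domain: StructureDomain) -> list[dict[str, int]]:
    """Per-residue map of backbone atom name -> atom index."""
    table = []
    for res in domain.residues:
        entry: dict[str, int] = {}
        for i in res.atom_indices:
            name = domain.atoms[i].name.strip().upper()
            if name in ("N", "CA", "C", "O", "H", "CB") and name not in entry:
                entry[name] = i
        table.append(entry)
    return table


def torsions(domain: StructureDomain) -> dict[str, np.ndarray]:
    """Backbone phi/psi per residue, with defined-masks and sin/cos.

    phi is undefined at the N-terminus, psi at the C-terminus; undefined
    angles are encoded as masked zeros (``phi_defined``/``psi_defined`` = 0)
    rather than NaN.  Missing backbone atoms mask the affected torsion with
    a warning.
    """
    xyz = domain.coordinates()
    bb = _backbone_index(domain)
    n = len(bb)
    phi = np.zeros(n)
    psi = np.zeros(n)
    phi_def = np.zeros(n, dtype=np.uint8)
    psi_def = np.zeros(n, dtype=np.uint8)

    def pos(res_idx: int, name: str):
        idx = bb[res_idx].get(name)
        return None if idx is None else xyz[idx]

    for i in range(n):
        if i > 0:
            pts = (pos(i - 1, "C"), pos(i, "N"), pos(i, "CA"), pos(i, "C"))
            if all(p is not None for p in pts):
                phi[i] = dihedral(*pts)
                phi_def[i] = 1
            else:
                warnings.warn(f"residue {i}: missing backbone atom, phi masked",
                              stacklevel=2)
        if i < n - 1:
            pts = (pos(i, "N"), pos(i, "CA"), pos(i, "C"), pos(i + 1, "N"))
            if all(p is not None for p in pts):
                psi[i] = dihedral(*pts)
                psi_def[i] = 1
            else:
                warnings.warn(f"residue {i}: missing backbone atom, psi masked",
                              stacklevel=2)

    rad = np.radians
    return {
        "phi": phi,
        "psi": psi,
        "phi_defined": phi_def,
        "psi_defined": psi_def,
        "phi_sin": np.where(phi_def, np.sin(rad(phi)), 0.0),
        "phi_cos": np.where(phi_def, np.cos(rad(phi)), 1.0),
        "psi_sin": np.where(psi_def, np.sin(rad(psi)), 0.0),
        "psi_cos": np.where(psi_def, np.cos(rad(psi)), 1.0),
    }


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander style)
# ---------------------------------------------------------------------------

SS8_STATES = ("H", "B", "E", "G", "I", "T", "S", "-")
SS8_COLUMNS = {
    "H": "is_regular_helix", "B": "is_beta_bridge", "E": "is_extended_strand",
    "G": "is_310_helix", "I": "is_pi_helix", "T": "is_hbond_turn",
    "S": "is_bend", "-": "no_ss",
}
SS3_OF_SS8 = {
    "H": "is_helix", "G": "is_helix", "I": "is_helix",
    "E": "is_sheet", "B": "is_sheet",
    "T": "Unk_SS", "S": "Unk_SS", "-": "Unk_SS",
}

_HBOND_CUTOFF = -0.5  # kcal/mol
_BEND_ANGLE = 70.0    # degrees


def _place_amide_h(n_pos, ca_pos, c_prev) -> np.ndarray:
    """Geometric amide hydrogen: 1.01 A from N along the in-plane bisector
    pointing away from both the previous carbonyl carbon and CA."""
    d1 = n_pos - c_prev
    d2 = n_pos - ca_pos
    d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
    d /= np.linalg.norm(d)
    return n_pos + 1.01 * d


def _hbond_energies(domain: StructureDomain) -> np.ndarray:
    """(n, n) Kabsch-Sander energies: E[i, j] = energy of the H-bond with
    donor NH(i) and acceptor C=O(j).  +inf where undefined."""
    xyz = domain.coordinates()
    bb = _backbone_index(domain)
    n = len(bb)
    E = np.full((n, n), np.inf)

    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if "H" in bb[i]:
            h_pos[i] = xyz[bb[i]["H"]]
        elif all(k in bb[i] for k in ("N", "CA")) and "C" in bb[i - 1] \
                and domain.residues[i].name.strip().upper() != "PRO":
            h_pos[i] = _place_amide_h(
                xyz[bb[i]["N"]], xyz[bb[i]["CA"]], xyz[bb[i - 1]["C"]]
            )

    for i in range(n):          # donor
        if "N" not in bb[i] or h_pos[i] is None:
            continue
        npos, hpos = xyz[bb[i]["N"]], h_pos[i]
        for j in range(n):      # acceptor
            if abs(i - j) < 2:
                continue
            if "C" not in bb[j] or "O" not in bb[j]:
                continue
            cpos, opos = xyz[bb[j]["C"]], xyz[bb[j]["O"]]
            r_on = np.linalg.norm(opos - npos)
            r_ch = np.linalg.norm(cpos - hpos)
            r_oh = np.linalg.norm(opos - hpos)
            r_cn = np.linalg.norm(cpos - npos)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            E[i, j] = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return E


def secondary_structure(domain: StructureDomain) -> tuple[list[str], list[str]]:
    """8-state and 3-state secondary structure labels per residue.

    Follows the Kabsch-Sander construction: backbone H-bonds below -0.5
    kcal/mol define n-turns (offsets 3/4/5 -> G/H/I helices when two
    consecutive turns start), and bridges (B isolated, E extended ladders);
    remaining turn residues are T; a Calpha pseudo-angle above 70 degrees is
    a bend (S); everything else '-'.  The 3-state collapse is
    {H,G,I}->helix, {E,B}->sheet, else loop.  Chains shorter than 3 residues
    are all '-'.
    """
    n = len(domain.residues)
    if n < 3:
        ss8 = ["-"] * n
        return ss8, [SS3_OF_SS8[s] for s in ss8]

    E = _hbond_energies(domain)
    hbond = E < _HBOND_CUTOFF  # hbond[i, j]: NH(i) -> CO(j)

    # n-turns: CO(i) accepts from NH(i+k)
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if hbond[i + k, i]:
                turn[k][i] = True

    ss8 = ["-"] * n

    # Bridges first collected, then helices override per DSSP priority H > E.
    parallel = np.zeros((n, n), dtype=bool)
    antiparallel = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (hbond[j, i - 1] and hbond[i + 1, j]) or (hbond[i, j - 1] and hbond[j + 1, i]):
                parallel[i, j] = parallel[j, i] = True
            if (hbond[i, j] and hbond[j, i]) or (hbond[j + 1, i - 1] and hbond[i + 1, j - 1]):
                antiparallel[i, j] = antiparallel[j, i] = True

    bridge = parallel | antiparallel
    is_bridge = bridge.any(axis=1)
    # Extended strands: bridges in consecutive residues form ladders (E);
    # isolated bridges are B.
    for i in range(n):
        if not is_bridge[i]:
            continue
        extended = (i > 0 and is_bridge[i - 1]) or (i + 1 < n and is_bridge[i + 1])
        ss8[i] = "E" if extended else "B"

    # Helices (alpha first: it wins ties with strands per DSSP priority).
    for i in range(1, n - 4):
        if turn[4][i] and turn[4][i - 1]:
            for j in range(i, i + 4):
                ss8[j] = "H"
    for k, label in ((3, "G"), (5, "I")):
        for i in range(1, n - k):
            if turn[k][i] and turn[k][i - 1]:
                for j in range(i, i + k):
                    if ss8[j] == "-":
                        ss8[j] = label

    # Turns: any residue inside an n-turn span not already assigned.
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                for j in range(i + 1, i + k):
                    if ss8[j] == "-":
                        ss8[j] = "T"

    # Bends: Calpha pseudo-angle.
    xyz = domain.coordinates()
    bb = _backbone_index(domain)
    for i in range(2, n - 2):
        if ss8[i] != "-":
            continue
        if not all("CA" in bb[j] for j in (i - 2, i, i + 2)):
            continue
        u = xyz[bb[i]["CA"]] - xyz[bb[i - 2]["CA"]]
        v = xyz[bb[i + 2]["CA"]] - xyz[bb[i]["CA"]]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))) > _BEND_ANGLE:
            ss8[i] = "S"

    return ss8, [SS3_OF_SS8[s] for s in ss8]


# ---------------------------------------------------------------------------
# Sequence entropy
# ---------------------------------------------------------------------------

def parse_fasta(text: str) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (header, sequence) pairs."""
    entries: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header = line[1:].strip()
            chunks = []
        else:
            chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


def sequence_entropy(msa_text: str, domain: StructureDomain) -> np.ndarray:
    """Per-residue normalized Shannon entropy from an aligned FASTA MSA.

    Column entropy is ``-sum p_a ln p_a`` over observed residue frequencies
    (gaps excluded), normalized by ln 20 so values lie in [0, 1]; all-gap
    columns score 1.0 (maximally uncertain).  Columns map onto the domain
    through the gapped first row, whose ungapped sequence must match the
    domain length.
    """
    rows = [seq.upper() for _, seq in parse_fasta(msa_text)]
    if not rows:
        raise ValueError("empty MSA")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("MSA rows have unequal lengths")

    first = rows[0]
    ungapped = [i for i, c in enumerate(first) if c != "-"]
    n_res = len(domain.residues)
    if len(ungapped) != n_res:
        raise ValueError(
            f"MSA first-row ungapped length {len(ungapped)} does not match "
            f"domain length {n_res}"
        )

    aa_set = set(SEQUENCE_AA)
    col_entropy = np.empty(width)
    for c in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[c]
            if ch in aa_set:
                counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            col_entropy[c] = 1.0
            continue
        p = np.array(list(counts.values()), dtype=float) / total
        col_entropy[c] = float(-(p * np.log(p)).sum() / math.log(20.0))

    return col_entropy[ungapped]
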