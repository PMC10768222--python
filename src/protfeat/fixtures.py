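"""Synthetic test structures: NeRF-built peptides, toy superfamilies, toy MSAs.

Everything any other module needs as input can be generated here from
(parameters, seed), with no downloads: backbone-only peptides with prescribed
phi/psi built by the natural-extension reference frame (NeRF) algorithm,
clustered families of mutated sequences with matching structures, and
alignments with prescribed column conservation.

The backbone geometry is the standard ideal peptide convention: bond lengths
N-CA 1.458, CA-C 1.525, C-N 1.329 A; angles N-CA-C 111.2, CA-C-N 116.2,
C-N-CA 121.7 degrees; omega fixed at 180 (trans).  The carbonyl O is placed
in the C(i) plane opposite N(i+1); CB by ideal tetrahedral geometry.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import ONE_TO_THREE, SEQUENCE_AA
from .datasplit import ClusterTable, pairwise_identity
from .structure import Atom, StructureDomain

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0

# Ideal-tetrahedral CB placement coefficients (from backbone N, CA, C).
_CB_COEF = (-0.58273431, 0.56802827, -0.54067466)


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom d so that |cd| = bond, angle(b,c,d) = angle, and the
    dihedral a-b-c-d equals torsion (natural-extension reference frame)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -math.cos(theta),
        math.sin(theta) * math.cos(chi),
        math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    domain_id: str = "peptide",
    chain_id: str = "A",
) -> StructureDomain:
    """Backbone (+CB) peptide with prescribed torsions.

    ``phi_psi[i]`` is (phi, psi) in degrees for residue i; phi of the first
    and psi of the last residue do not affect the backbone and are ignored.
    Recomputing torsions on the output recovers the inputs for interior
    residues.  Glycine gets no CB.
    """
    if len(sequence) != len(phi_psi):
        raise ValueError(
            f"sequence length {len(sequence)} != torsion list length {len(phi_psi)}"
        )
    if not sequence:
        raise ValueError("empty sequence")
    n_res = len(sequence)

    # Backbone trace.
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    alpha = math.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(alpha), math.sin(alpha), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        N[i] = nerf_place(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = nerf_place(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[i] = nerf_place(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])

    domain = StructureDomain(domain_id=domain_id)
    serial = 1

    def add(name: str, element: str, pos: np.ndarray, res_idx: int, resname: str):
        nonlocal serial
        domain.atoms.append(Atom(
            serial=serial, name=name, altloc="", residue_name=resname,
            chain_id=chain_id, residue_seq=res_idx + 1, insertion_code="",
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            occupancy=1.0, bfactor=0.0, element=element, is_hetero=False,
        ))
        serial += 1

    for i, letter in enumerate(sequence):
        try:
            resname = ONE_TO_THREE[letter.upper()]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter {letter!r}") from None
        add("N", "N", N[i], i, resname)
        add("CA", "C", CA[i], i, resname)
        add("C", "C", C[i], i, resname)
        # Carbonyl O: in-plane, opposite the next amide N (or by psi torsion
        # at the C-terminus).
        if i + 1 < n_res:
            u = N[i + 1] - C[i]
            v = CA[i] - C[i]
            d = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            o_pos = C[i] + BOND_C_O * d / np.linalg.norm(d)
        else:
            o_pos = nerf_place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                               phi_psi[i][1] + 180.0)
        add("O", "O", o_pos, i, resname)
        if resname != "GLY":
            b = CA[i] - N[i]
            c = C[i] - CA[i]
            a = np.cross(b, c)
            cb = _CB_COEF[0] * a + _CB_COEF[1] * b + _CB_COEF[2] * c + CA[i]
            add("CB", "C", cb, i, resname)
    return domain


HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def build_helix(n: int = 15, sequence: str | None = None,
                domain_id: str = "helix") -> StructureDomain:
    """Ideal alpha-helix of n residues (ALA by default)."""
    seq = sequence or "A" * n
    return build_peptide(seq, [HELIX_PHI_PSI] * len(seq), domain_id=domain_id)


def build_strand(n: int = 8, sequence: str | None = None,
                 domain_id: str = "strand") -> StructureDomain:
    """Fully extended strand of n residues."""
    seq = sequence or "A" * n
    return build_peptide(seq, [STRAND_PHI_PSI] * len(seq), domain_id=domain_id)


def _two_strand_domain(strand_a: StructureDomain, xyz_b: np.ndarray,
                       n: int, domain_id: str) -> StructureDomain:
    domain = StructureDomain(domain_id=domain_id)
    serial = 1
    for pass_idx, coords in enumerate((strand_a.coordinates(), xyz_b)):
        for i, atom in enumerate(strand_a.atoms):
            domain.atoms.append(Atom(
                serial=serial, name=atom.name, altloc="",
                residue_name=atom.residue_name, chain_id="A",
                residue_seq=atom.residue_seq + pass_idx * (n + 2),
                insertion_code="",
                x=float(coords[i][0]), y=float(coords[i][1]), z=float(coords[i][2]),
                element=atom.element, is_hetero=False,
            ))
            serial += 1
    return domain


def build_sheet_pair(n: int = 6, domain_id: str = "sheet") -> StructureDomain:
    """Synthetic two-strand antiparallel beta-sheet.

    Builds one extended strand, generates the partner by the two-fold
    rotation about the sheet normal that relates antiparallel strands, and
    picks the interstrand separation and axial registry shift that maximize
    the number of backbone hydrogen bonds (Kabsch-Sander energy below the
    bonding cutoff) between the strands.  A constructed stand-in for a real
    sheet, adequate for exercising hydrogen-bond pattern detection.
    """
    from .calculators import _hbond_energies

    strand_a = build_strand(n, domain_id=domain_id)
    xyz = strand_a.coordinates()
    ca_idx = [i for i, a in enumerate(strand_a.atoms) if a.name == "CA"]
    axis = xyz[ca_idx[-1]] - xyz[ca_idx[0]]
    axis /= np.linalg.norm(axis)
    mid = xyz[ca_idx].mean(axis=0)
    # In-plane interstrand direction: first carbonyl O direction off-axis.
    o_idx = [i for i, a in enumerate(strand_a.atoms) if a.name == "O"][0]
    c_idx = [i for i, a in enumerate(strand_a.atoms) if a.name == "C"][0]
    perp = xyz[o_idx] - xyz[c_idx]
    perp -= np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    normal = np.cross(axis, perp)
    rot = 2.0 * np.outer(normal, normal) - np.eye(3)  # C2 about sheet normal

    best = None
    for sep in np.arange(4.4, 5.6, 0.1):
        for shift in np.arange(-3.4, 3.5, 0.2):
            center = mid + 0.5 * sep * perp + 0.5 * shift * axis
            xyz_b = (xyz - center) @ rot.T + center
            candidate = _two_strand_domain(strand_a, xyz_b, n, domain_id)
            E = _hbond_energies(candidate)
            inter = E[:n, n:].min(initial=0.0), E[n:, :n].min(initial=0.0)
            n_bonds = int((E[:n, n:] < -0.5).sum() + (E[n:, :n] < -0.5).sum())
            key = (n_bonds, -min(inter))
            if best is None or key > best[0]:
                best = (key, candidate)
    return best[1]


# ---------------------------------------------------------------------------
# Toy superfamilies and MSAs
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int,
                     alphabet: str | None = None) -> str:
    pool = alphabet or "".join(SEQUENCE_AA)
    return "".join(rng.choice(list(pool), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.05) -> str:
    """Point-mutate ~rate of positions (at least one, identity >= 90%)."""
    n_mut = max(1, int(round(rate * len(seq))))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in SEQUENCE_AA if a != out[p]]
        out[p] = str(rng.choice(choices))
    return "".join(out)


def make_toy_superfamily(
    n_clusters: int,
    domains_per_cluster: int,
    seed: int = 0,
    length: int = 40,
    superfamily: str = "2.60.40.10",
    identity_threshold: float = 0.35,
) -> tuple[list[tuple[str, StructureDomain, str]], ClusterTable]:
    """Synthetic superfamily with known cluster structure.

    Within a cluster, sequences are >= 90%-identity point mutants of a random
    base; between clusters, bases are drawn from disjoint random sub-alphabets
    and re-drawn until all pairwise representative identities fall below the
    threshold, so the ground truth is recoverable by identity clustering.
    Structures are NeRF-built with a per-cluster torsion profile (alternating
    helical and extended clusters).
    """
    if n_clusters < 1 or domains_per_cluster < 1:
        raise ValueError("cluster counts must be positive")
    rng = np.random.default_rng(seed)

    bases: list[str] = []
    for k in range(n_clusters):
        alphabet = "".join(rng.choice(list(SEQUENCE_AA), size=8, replace=False))
        for _ in range(50):
            candidate = _random_sequence(rng, length, alphabet)
            if all(pairwise_identity(candidate, b) < identity_threshold - 0.05
                   for b in bases):
                bases.append(candidate)
                break
        else:
            raise RuntimeError("could not construct well-separated cluster bases")

    domains: list[tuple[str, StructureDomain, str]] = []
    assignments: dict[str, int] = {}
    for k, base in enumerate(bases):
        profile = HELIX_PHI_PSI if k % 2 == 0 else STRAND_PHI_PSI
        for m in range(domains_per_cluster):
            seq = base if m == 0 else _mutate(rng, base)
            domain_id = f"d{k:02d}m{m:02d}"
            structure = build_peptide(seq, [profile] * len(seq), domain_id=domain_id)
            structure.superfamily = superfamily
            domains.append((domain_id, structure, seq))
            assignments[domain_id] = k
    return domains, ClusterTable(assignments=assignments,
                                 threshold=identity_threshold)


def make_toy_msa(
    length: int,
    conserved_positions: list[int],
    n_rows: int,
    seed: int = 0,
    first_row: str | None = None,
) -> str:
    """Aligned FASTA with prescribed conservation.

    Conserved columns carry a single residue in every row; all other columns
    are uniform over the 20 amino acids.  ``first_row`` pins row 1 (e.g. to a
    domain's sequence) and the conserved residues to match it.
    """
    if any(p < 0 or p >= length for p in conserved_positions):
        raise ValueError("conserved positions out of range")
    if first_row is not None and len(first_row) != length:
        raise ValueError("first_row length mismatch")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    col_residue = {
        p: (first_row[p] if first_row is not None else str(rng.choice(list(SEQUENCE_AA))))
        for p in conserved
    }
    rows = []
    for r in range(n_rows):
        if r == 0 and first_row is not None:
            rows.append(first_row)
            continue
        chars = [
            col_residue[c] if c in conserved else str(rng.choice(list(SEQUENCE_AA)))
            for c in range(length)
        ]
        rows.append("".join(chars))
    return "".join(f">seq{r}\n{row}\n" for r, row in enumerate(rows))
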