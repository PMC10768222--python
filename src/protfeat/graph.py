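"""Residue-level contact graphs with geometric edge features.

Nodes are residues (carrying their feature rows); an edge exists between two
residues when the minimum distance over their heavy-atom pairs is within the
cutoff (5 A by default, capturing van der Waals and other noncovalent
contacts), or between all pairs in fully-connected mode.  Each edge carries
the Calpha-Calpha distance, the minimum heavy-atom distance, the sequence
separation, and the Calpha-Cbeta-Cbeta-Calpha inter-residue dihedral (masked
when either residue lacks a Cbeta, i.e. glycine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calculators import dihedral
from .structure import StructureDomain

EDGE_COLUMNS = ["i", "j", "distance_ca", "distance_min", "seq_separation",
                "omega_dihedral", "omega_defined"]


@dataclass
class Edge:
    i: int
    j: int
    distance_ca: float
    distance_min: float
    seq_separation: int
    omega_dihedral: float
    omega_defined: bool


@dataclass
class ResidueGraph:
    n_nodes: int
    edges: list[Edge] = field(default_factory=list)
    node_features: pd.DataFrame | None = None

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (e.i, e.j, e.distance_ca, e.distance_min, e.seq_separation,
             e.omega_dihedral, int(e.omega_defined))
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def build_residue_graph(
    domain: StructureDomain,
    feature_table: pd.DataFrame | None = None,
    cutoff: float = 5.0,
    mode: str = "contact",
) -> ResidueGraph:
    """Build the residue graph of a sanitized domain.

    ``mode='contact'`` connects residues whose minimum heavy-atom distance
    is <= ``cutoff``; ``mode='full'`` connects all pairs.  Edges are stored
    once with i < j.
    """
    if mode not in ("contact", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "contact" and cutoff <= 0:
        raise ValueError("cutoff must be positive in contact mode")

    residues = domain.residues
    xyz = domain.coordinates()
    heavy: list[np.ndarray] = []
    ca: list[np.ndarray | None] = []
    cb: list[np.ndarray | None] = []
    for res in residues:
        idx = [i for i in res.atom_indices
               if domain.atoms[i].element.upper() != "H"]
        heavy.append(xyz[idx] if idx else np.empty((0, 3)))
        ca_idx = [i for i in res.atom_indices
                  if domain.atoms[i].name.strip().upper() == "CA"]
        cb_idx = [i for i in res.atom_indices
                  if domain.atoms[i].name.strip().upper() == "CB"]
        ca.append(xyz[ca_idx[0]] if ca_idx else None)
        cb.append(xyz[cb_idx[0]] if cb_idx else None)

    graph = ResidueGraph(n_nodes=len(residues), node_features=feature_table)
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if heavy[i].shape[0] == 0 or heavy[j].shape[0] == 0:
                continue
            d2 = ((heavy[i][:, None, :] - heavy[j][None, :, :]) ** 2).sum(axis=-1)
            dmin = float(np.sqrt(d2.min()))
            if mode == "contact" and dmin > cutoff:
                continue
            dca = (float(np.linalg.norm(ca[i] - ca[j]))
                   if ca[i] is not None and ca[j] is not None else float("nan"))
            if ca[i] is not None and cb[i] is not None \
                    and ca[j] is not None and cb[j] is not None:
                omega = dihedral(ca[i], cb[i], cb[j], ca[j])
                defined = True
            else:
                omega, defined = 0.0, False
            graph.edges.append(Edge(i, j, dca, dmin, j - i, omega, defined))
    return graph


def adjacency(graph: ResidueGraph) -> np.ndarray:
    """Symmetric 0/1 adjacency matrix with zero diagonal (a contact map)."""
    mat = np.zeros((graph.n_nodes, graph.n_nodes), dtype=np.uint8)
    for e in graph.edges:
        mat[e.i, e.j] = mat[e.j, e.i] = 1
    return mat
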