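"""Sequence-identity clustering and leakage-free train/validation/test splits.

Homologous proteins appearing on both sides of a split leak evolutionary
signal and inflate apparent model performance.  The remedy implemented here
mirrors sequence-identity culling: domains are clustered greedily at a
pairwise-identity threshold (0.35 by default, matching 35%-identity culling;
0.20 for the stricter guideline), and splits are assigned to *whole
clusters* so no pair of similar sequences straddles a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

SPLIT_NAMES = ("train", "validation", "test")


@dataclass
class ClusterTable:
    assignments: dict[str, int]
    threshold: float
    representatives: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for d, c in self.assignments.items():
            out.setdefault(c, []).append(d)
        return out


@dataclass
class SplitAssignment:
    assignments: dict[str, str]     # domain_id -> split name
    fractions: tuple[float, float, float]
    seed: int

    def domains_in(self, split: str) -> list[str]:
        return [d for d, s in self.assignments.items() if s == split]

    def realized_fractions(self) -> dict[str, float]:
        n = len(self.assignments)
        return {s: (len(self.domains_in(s)) / n if n else 0.0) for s in SPLIT_NAMES}


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    # End gaps penalized too (true global alignment).
    return a


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length.

    Scoring: match +1, mismatch 0, linear gap -1 with end gaps penalized.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    matches = 0
    length = 0
    a_row, b_row = str(alignment[0]), str(alignment[1])
    for ca, cb in zip(a_row, b_row):
        length += 1
        if ca == cb and ca != "-":
            matches += 1
    return matches / length


def cluster_sequences(
    sequences: dict[str, str],
    threshold: float = 0.35,
) -> ClusterTable:
    """Greedy incremental clustering by identity to cluster representatives.

    Sequences are processed longest-first (ties broken by identifier) so the
    result is independent of the input dictionary order; each sequence joins
    the first existing cluster whose representative matches at or above the
    threshold, else founds a new cluster with itself as representative.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda d: (-len(sequences[d]), d))
    reps: list[tuple[int, str]] = []  # (cluster_id, representative sequence)
    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    next_id = 0
    for dom in order:
        seq = sequences[dom]
        for cid, rep_seq in reps:
            if pairwise_identity(seq, rep_seq) >= threshold:
                assignments[dom] = cid
                break
        else:
            assignments[dom] = next_id
            reps.append((next_id, seq))
            representatives[next_id] = dom
            next_id += 1
    return ClusterTable(assignments=assignments, threshold=threshold,
                        representatives=representatives)


def make_splits(
    clusters: ClusterTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/validation/test bins.

    Clusters are shuffled by a seeded generator, then placed greedily in the
    bin with the largest remaining deficit (target domain count minus
    current count); ties go to the earlier bin (train > validation > test).
    Deterministic for a given seed; never splits a cluster.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    members = clusters.members()
    if len(members) < len(SPLIT_NAMES):
        raise ValueError(
            f"need at least {len(SPLIT_NAMES)} clusters to fill all splits, "
            f"got {len(members)}"
        )
    total = sum(len(v) for v in members.values())
    targets = [f * total for f in fractions]
    counts = [0.0, 0.0, 0.0]

    rng = np.random.default_rng(seed)
    cluster_ids = sorted(members)
    rng.shuffle(cluster_ids)

    assignments: dict[str, str] = {}
    for cid in cluster_ids:
        deficits = [targets[b] - counts[b] for b in range(3)]
        bin_idx = int(np.argmax(deficits))
        counts[bin_idx] += len(members[cid])
        for dom in members[cid]:
            assignments[dom] = SPLIT_NAMES[bin_idx]
    return SplitAssignment(assignments=assignments,
                           fractions=tuple(fractions), seed=seed)


@dataclass
class LeakageReport:
    violations: list[int]               # cluster ids spanning >1 split
    realized_fractions: dict[str, float]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        fr = ", ".join(f"{s}={f:.3f}" for s, f in self.realized_fractions.items())
        return (f"leakage violations: {len(self.violations)} "
                f"({self.violations}); realized fractions: {fr}")


def audit_leakage(assignment: SplitAssignment, clusters: ClusterTable) -> LeakageReport:
    """Verify that no cluster spans more than one split."""
    missing = set(assignment.assignments) ^ set(clusters.assignments)
    if missing:
        raise ValueError(
            f"domain coverage mismatch between split and cluster tables: "
            f"{sorted(missing)[:5]}..."
        )
    violations = []
    for cid, doms in clusters.members().items():
        splits = {assignment.assignments[d] for d in doms}
        if len(splits) > 1:
            violations.append(cid)
    fr = {s: round(f, 3) for s, f in assignment.realized_fractions().items()}
    return LeakageReport(violations=sorted(violations), realized_fractions=fr)


# ---------------------------------------------------------------------------
# TSV import/export
# ---------------------------------------------------------------------------

def write_cluster_tsv(clusters: ClusterTable) -> str:
    lines = [f"{d}\t{c}" for d, c in sorted(clusters.assignments.items())]
    return "\n".join(lines) + "\n"


def read_cluster_tsv(text: str, threshold: float = 0.35) -> ClusterTable:
    assignments = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        dom, cid = line.split("\t")
        assignments[dom] = int(cid)
    return ClusterTable(assignments=assignments, threshold=threshold)


def write_split_tsv(assignment: SplitAssignment) -> str:
    lines = [f"{d}\t{s}" for d, s in sorted(assignment.assignments.items())]
    return "\n".join(lines) + "\n"


def read_split_tsv(text: str, seed: int = 0) -> SplitAssignment:
    assignments = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        dom, split = line.split("\t")
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split name {split!r}")
        assignments[dom] = split
    return SplitAssignment(assignments=assignments, fractions=(0.8, 0.1, 0.1),
                           seed=seed)
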