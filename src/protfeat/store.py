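"""Hierarchical HDF5 dataset store mirroring the domain-classification tree.

Layout::

    /<C>/<A>/<T>/<H>/domains/<domain_id>/{atoms,residues,edges}
    /<C>/<A>/<T>/<H>/data_splits/{train,validation,test}/<domain_id>

where ``<C>/<A>/<T>/<H>`` is the 4-level superfamily code with '/'
separators (e.g. ``2/60/40/10``).  Split entries are HDF5 *hard links* to
the domain groups — a second path aliasing the same stored object, so split
listings never copy data.  Feature matrices are stored as compound-dtype
tables: one-hot/Boolean columns as unsigned 8-bit, continuous columns as
32-bit floats.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .datasplit import SPLIT_NAMES, SplitAssignment
from .featurize import FeatureTable
from .graph import EDGE_COLUMNS, ResidueGraph
from .schema import FeatureSchema, default_schema

FORMAT_VERSION = "1.0"

_SAFE_ID = re.compile(r"[^A-Za-z0-9._-]")


def sanitize_domain_id(domain_id: str) -> str:
    """Restrict domain ids to link-safe characters (alnum plus . _ -)."""
    return _SAFE_ID.sub("_", domain_id)


def superfamily_path(code: str) -> str:
    """Normalize a 4-level superfamily code to its '/'-separated group key.

    Accepts '.'- or '/'-separated forms ('2.60.40.10' or '2/60/40/10').
    """
    parts = re.split(r"[./]", code.strip())
    if len(parts) != 4 or not all(p.isdigit() for p in parts):
        raise ValueError(
            f"superfamily code {code!r} is not a 4-level dotted/slashed "
            "numeric code like 2.60.40.10"
        )
    return "/".join(parts)


class HierStore:
    """Handle to the hierarchical container (h5py.File wrapper)."""

    def __init__(self, handle: h5py.File):
        self.h5 = handle

    # -- lifecycle ----------------------------------------------------------

    @classmethod
    def create(cls, path: str | Path, force: bool = False) -> "HierStore":
        path = Path(path)
        if path.exists() and not force:
            raise FileExistsError(
                f"{path} already exists; pass force=True to overwrite"
            )
        handle = h5py.File(path, "w")
        handle.attrs["format_version"] = FORMAT_VERSION
        return cls(handle)

    @classmethod
    def open(cls, path: str | Path, mode: str = "r") -> "HierStore":
        return cls(h5py.File(Path(path), mode))

    def close(self) -> None:
        self.h5.close()

    def __enter__(self) -> "HierStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing -------------------------------------------------------------

    def write_domain(
        self,
        superfamily: str,
        domain_id: str,
        feature_table: FeatureTable,
        graph: ResidueGraph | None = None,
        schema: FeatureSchema | None = None,
        overwrite: bool = False,
    ) -> str:
        """Write atoms/residues/edges datasets for one domain; returns the
        domain group path."""
        schema = schema or default_schema()
        sf = superfamily_path(superfamily)
        did = sanitize_domain_id(domain_id)
        group_path = f"{sf}/domains/{did}"
        if group_path in self.h5:
            if not overwrite:
                raise ValueError(
                    f"domain {domain_id!r} already stored; pass overwrite=True"
                )
            del self.h5[group_path]
        grp = self.h5.require_group(group_path)
        grp.create_dataset("atoms", data=_frame_to_table(feature_table.atoms, schema))
        grp.create_dataset("residues",
                           data=_frame_to_table(feature_table.residues, schema))
        if graph is not None:
            grp.create_dataset("edges", data=_edges_to_table(graph))
        return group_path

    def link_splits(
        self,
        superfamily: str,
        assignment: SplitAssignment,
    ) -> dict[str, int]:
        """Hard-link every assigned domain under data_splits/<split>/.

        Idempotent; raises if a referenced domain has not been written.
        """
        sf = superfamily_path(superfamily)
        counts = {s: 0 for s in SPLIT_NAMES}
        for s in SPLIT_NAMES:
            self.h5.require_group(f"{sf}/data_splits/{s}")
        for domain_id, split in sorted(assignment.assignments.items()):
            did = sanitize_domain_id(domain_id)
            src = f"{sf}/domains/{did}"
            if src not in self.h5:
                raise KeyError(
                    f"split references domain {domain_id!r} which is not in "
                    "the store"
                )
            split_grp = self.h5.require_group(f"{sf}/data_splits/{split}")
            if did not in split_grp:
                split_grp[did] = self.h5[src]  # hard link, not a copy
            counts[split] += 1
        return counts

    # -- reading -------------------------------------------------------------

    def superfamilies(self) -> list[str]:
        """All 4-level codes present, '/'-separated."""
        found = []

        def visit(name, obj):
            if isinstance(obj, h5py.Group) and name.count("/") == 3 \
                    and "domains" in obj:
                found.append(name)

        self.h5.visititems(visit)
        return sorted(found)

    def domain_ids(self, superfamily: str) -> list[str]:
        sf = superfamily_path(superfamily)
        grp = self.h5.get(f"{sf}/domains")
        return sorted(grp.keys()) if grp else []

    def read_domain(self, superfamily: str, domain_id: str, via_split: str | None = None):
        """Read (atoms, residues, edges) arrays for a domain, optionally
        through its split alias path."""
        sf = superfamily_path(superfamily)
        did = sanitize_domain_id(domain_id)
        base = (f"{sf}/data_splits/{via_split}/{did}" if via_split
                else f"{sf}/domains/{did}")
        grp = self.h5[base]
        edges = grp["edges"][...] if "edges" in grp else None
        return grp["atoms"][...], grp["residues"][...], edges

    def iterate_split(
        self,
        superfamily: str,
        split: str,
        batch_size: int = 1,
        shuffle_seed: int | None = None,
    ) -> Iterator[list[tuple[str, np.ndarray, np.ndarray, np.ndarray | None]]]:
        """Yield batches of (domain_id, atoms, residues, edges).

        Every linked domain appears exactly once per pass; order is
        deterministic under a fixed shuffle seed (sorted when no seed).
        Read-only, so concurrent readers are safe.
        """
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}; expected {SPLIT_NAMES}")
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        sf = superfamily_path(superfamily)
        grp = self.h5.get(f"{sf}/data_splits/{split}")
        ids = sorted(grp.keys()) if grp else []
        if shuffle_seed is not None:
            rng = np.random.default_rng(shuffle_seed)
            ids = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        batch = []
        for did in ids:
            dgrp = grp[did]
            edges = dgrp["edges"][...] if "edges" in dgrp else None
            batch.append((did, dgrp["atoms"][...], dgrp["residues"][...], edges))
            if len(batch) == batch_size:
                yield batch
                batch = []
        if batch:
            yield batch

    def export_summary(self) -> pd.DataFrame:
        """Per-superfamily counts: (superfamily, n_domains, n_train, n_val,
        n_test)."""
        rows = []
        for sf in self.superfamilies():
            grp = self.h5[sf]
            n_domains = len(grp["domains"]) if "domains" in grp else 0
            counts = []
            for split in SPLIT_NAMES:
                sgrp = grp.get(f"data_splits/{split}")
                counts.append(len(sgrp) if sgrp else 0)
            rows.append((sf.replace("/", "."), n_domains, *counts))
        return pd.DataFrame(
            rows, columns=["superfamily", "n_domains", "n_train", "n_val", "n_test"]
        )


# ---------------------------------------------------------------------------
# Compound-dtype conversion
# ---------------------------------------------------------------------------

def _frame_to_table(frame: pd.DataFrame, schema: FeatureSchema) -> np.ndarray:
    """Feature frame -> structured array (u1 for one-hots/booleans, f4 for
    continuous)."""
    fields = []
    for col in frame.columns:
        dtype = schema.dtype(col) if col in schema else "f4"
        fields.append((col, np.uint8 if dtype == "u1" else np.float32))
    table = np.empty(len(frame), dtype=np.dtype(fields))
    for col, np_dtype in fields:
        table[col] = frame[col].to_numpy().astype(np_dtype)
    return table


def table_to_frame(table: np.ndarray) -> pd.DataFrame:
    """Structured array back to a DataFrame (column order preserved)."""
    return pd.DataFrame({name: table[name] for name in table.dtype.names})


_EDGE_DTYPES = {
    "i": np.int32, "j": np.int32, "distance_ca": np.float32,
    "distance_min": np.float32, "seq_separation": np.int32,
    "omega_dihedral": np.float32, "omega_defined": np.uint8,
}


def _edges_to_table(graph: ResidueGraph) -> np.ndarray:
    frame = graph.edge_frame()
    fields = [(c, _EDGE_DTYPES[c]) for c in EDGE_COLUMNS]
    table = np.empty(len(frame), dtype=np.dtype(fields))
    for c, dt in fields:
        table[c] = frame[c].to_numpy().astype(dt)
    return table


def init_store(path: str | Path, force: bool = False) -> HierStore:
    """Create an empty store with a format-version attribute."""
    return HierStore.create(path, force=force)
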