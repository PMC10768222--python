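"""The feature schema: names, levels and aggregation rules.

The full rule table (~100 rows) ships with the package as
``data/feature_schema.csv`` — a single machine-readable source of truth for
which features exist, whether they live at the atom or residue level, how
they aggregate into voxels (max/mean/sum/min), and how atom-level features
roll up to residues (or residue-level features map down onto child atoms).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

VALID_VOXEL_AGGS = {"max", "mean", "sum", "min"}
VALID_RESIDUE_AGGS = {"max", "mean", "sum", "min", "map_down", "none"}


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    level: str            # "atom" or "residue"
    group: str            # one-hot block / flag / continuous / boolean / mask
    voxel_agg: str        # max | mean | sum | min
    residue_agg: str      # max | mean | sum | min | map_down | none
    dtype: str            # "u1" (one-hot/boolean) or "f4" (continuous)
    source: str           # calculator or provider name


class FeatureSchema:
    """Ordered feature entries plus lookup helpers."""

    def __init__(self, entries: list[FeatureEntry]):
        if not entries:
            raise ValueError("empty feature schema")
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        for e in entries:
            if e.voxel_agg not in VALID_VOXEL_AGGS:
                raise ValueError(f"{e.name}: invalid voxel_agg {e.voxel_agg!r}")
            if e.residue_agg not in VALID_RESIDUE_AGGS:
                raise ValueError(f"{e.name}: invalid residue_agg {e.residue_agg!r}")
            if e.level not in ("atom", "residue"):
                raise ValueError(f"{e.name}: invalid level {e.level!r}")
        self.entries = list(entries)
        self._by_name = {e.name: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureEntry:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def group(self, group: str) -> list[FeatureEntry]:
        return [e for e in self.entries if e.group == group]

    def atom_columns(self) -> list[str]:
        """Every feature appears on atoms (residue features map down)."""
        return self.names

    def residue_columns(self) -> list[str]:
        """Features present on residues: residue-level ones plus atom-level
        ones that carry a residue aggregation rule."""
        out = []
        for e in self.entries:
            if e.level == "residue" or e.residue_agg not in ("none", "map_down"):
                out.append(e.name)
            elif e.group == "boolean":
                # Booleans re-discretized from residue-level sources.
                out.append(e.name)
        return out

    def voxel_agg(self, name: str) -> str:
        return self._by_name[name].voxel_agg

    def dtype(self, name: str) -> str:
        return self._by_name[name].dtype


def load_schema(path: str | Path | None = None) -> FeatureSchema:
    """Load the shipped default schema, or an override CSV."""
    if path is None:
        ref = resources.files("protfeat") / "data" / "feature_schema.csv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries = [
        FeatureEntry(
            name=row["name"], level=row["level"], group=row["group"],
            voxel_agg=row["voxel_agg"], residue_agg=row["residue_agg"],
            dtype=row["dtype"], source=row["source"],
        )
        for row in csv.DictReader(text.splitlines())
    ]
    return FeatureSchema(entries)


_DEFAULT: FeatureSchema | None = None


def default_schema() -> FeatureSchema:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_schema()
    return _DEFAULT
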