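"""Aggregation rules and Boolean discretization.

Atom-level features roll up to residues (sum/mean/max/min per the schema),
residue-level features map down unchanged onto child atoms, and the seven
Boolean features are thresholded from their continuous sources with the
printed relations applied exactly (no epsilon: charge 0 is neither negative
nor positive; rasa exactly 0.2 is not buried; cx exactly 2 is concave).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema

_OPS = {
    "max": np.max,
    "mean": np.mean,
    "sum": np.sum,
    "min": np.min,
}


def aggregate(values, op: str) -> float:
    """Apply a named aggregation (max/mean/sum/min) to a non-empty list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty group")
    try:
        fn = _OPS[op]
    except KeyError:
        raise ValueError(f"unknown aggregation op {op!r}") from None
    return float(fn(arr))


@dataclass(frozen=True)
class BooleanRule:
    boolean_name: str
    source_feature: str
    relation: str       # "<", ">", "<="
    threshold: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.relation == "<":
            return (v < self.threshold).astype(np.uint8)
        if self.relation == ">":
            return (v > self.threshold).astype(np.uint8)
        if self.relation == "<=":
            return (v <= self.threshold).astype(np.uint8)
        raise ValueError(f"unknown relation {self.relation!r}")


#: The seven discretization rules, with relations exactly as printed.
BOOLEAN_RULES: tuple[BooleanRule, ...] = (
    BooleanRule("neg_charge", "charge", "<", 0.0),
    BooleanRule("pos_charge", "charge", ">", 0.0),
    BooleanRule("is_electronegative", "electrostatic_potential", "<", 0.0),
    BooleanRule("is_concave", "cx", "<=", 2.0),
    BooleanRule("is_hydrophobic", "hydrophobicity", ">", 0.0),
    BooleanRule("residue_buried", "residue_rasa", "<", 0.2),
    BooleanRule("is_conserved", "eppic_entropy", "<", 0.5),
)


def discretize(frame: pd.DataFrame, rules=BOOLEAN_RULES, strict: bool = False) -> pd.DataFrame:
    """Boolean columns thresholded from continuous sources present in
    ``frame``.  With ``strict`` a missing source feature raises; otherwise
    the corresponding Boolean is simply skipped (e.g., atom-level frames
    lack residue_rasa before map-down)."""
    out = {}
    for rule in rules:
        if rule.source_feature not in frame.columns:
            if strict:
                raise KeyError(
                    f"source feature {rule.source_feature!r} required by "
                    f"{rule.boolean_name!r} is missing"
                )
            continue
        out[rule.boolean_name] = rule.apply(frame[rule.source_feature].to_numpy())
    return pd.DataFrame(out, index=frame.index)


def atoms_to_residues(
    atom_frame: pd.DataFrame,
    residue_of_atom: np.ndarray,
    n_residues: int,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Aggregate atom-level features onto residues per the schema rules.

    Only features with a numeric residue rule (sum/mean/max/min) are
    aggregated; map-down and atom-only features are skipped (the residue
    identity one-hots are recomputed by the featurizer, not aggregated).
    """
    schema = schema or default_schema()
    residue_of_atom = np.asarray(residue_of_atom)
    out: dict[str, np.ndarray] = {}
    for name in atom_frame.columns:
        if name not in schema:
            continue
        rule = schema[name].residue_agg
        if rule in ("none", "map_down"):
            continue
        values = atom_frame[name].to_numpy(dtype=float)
        agg = np.empty(n_residues)
        for r in range(n_residues):
            group = values[residue_of_atom == r]
            agg[r] = aggregate(group, rule)
        out[name] = agg
    return pd.DataFrame(out)


def map_down(residue_frame: pd.DataFrame, residue_of_atom: np.ndarray,
             columns: list[str]) -> pd.DataFrame:
    """Replicate residue-level columns onto child atoms unchanged."""
    idx = np.asarray(residue_of_atom)
    return pd.DataFrame(
        {c: residue_frame[c].to_numpy()[idx] for c in columns}
    )
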