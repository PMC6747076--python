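"""Substituent enumeration and CEI prediction for designed derivatives.

Starting from a template molecule carrying labelled attachment points
("pos1", "pos5" — the ring positions flagged by the contour maps), every
single substitution at each position and every double substitution is
enumerated: |P1| + |P5| + |P1|*|P5| structures.  With the standard group
sets (6 at position 1, 6 at position 5) that is the 48-derivative library.

Fragment geometries are idealized: each group is a small rigid template
with standard bond lengths, oriented along the exit vector of the atom it
replaces.  No conformer search is attempted — the attachment chemistry of
the carbonyl and ethynyl caps in particular is a best-effort placement.

Predicted CEIs can come from the live field -> descriptor -> PLS chain
(synthetic or user data) or be supplied directly from an external table, in
which case only the ranking arithmetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .field_engine import (
    Atom,
    CARBON_PROBE,
    DescriptorTable,
    Molecule,
    compute_field_block,
)
from .fuzzy_eval import relative_change
from .pls_model import PLSModel, predict

__all__ = [
    "DerivativeRecord",
    "POSITION1_GROUPS",
    "POSITION5_GROUPS",
    "GROUP_DISPLAY_NAMES",
    "enumerate_derivatives",
    "predict_derivative_cei",
    "attach_changes",
    "summarize_reduction_range",
]

# local fragment frames: +z points outward along the exit vector of the
# replaced placeholder atom, origin at the anchor (bonded scaffold atom).
# entries: (element, (x, y, z) offset in A, partial charge in e)
_FRAGMENTS: dict[str, list[tuple[str, tuple[float, float, float], float]]] = {
    "CH3": [
        ("C", (0.0, 0.0, 1.47), -0.10),
        ("H", (1.03, 0.0, 1.83), 0.05),
        ("H", (-0.51, 0.89, 1.83), 0.05),
        ("H", (-0.51, -0.89, 1.83), 0.05),
    ],
    "H": [("H", (0.0, 0.0, 1.01), 0.15)],
    "C2H5": [
        ("C", (0.0, 0.0, 1.47), -0.08),
        ("H", (1.02, 0.0, 1.82), 0.04),
        ("H", (-0.51, 0.88, 1.82), 0.04),
        ("C", (-0.48, -0.84, 2.41), -0.12),
        ("H", (0.03, -1.76, 2.35), 0.04),
        ("H", (-1.54, -1.03, 2.23), 0.04),
        ("H", (-0.36, -0.45, 3.42), 0.04),
    ],
    "C2H3": [
        ("C", (0.0, 0.0, 1.47), -0.05),
        ("H", (1.04, 0.0, 1.77), 0.05),
        ("C", (-0.95, 0.0, 2.40), -0.20),
        ("H", (-1.97, 0.0, 2.07), 0.10),
        ("H", (-0.74, 0.0, 3.45), 0.10),
    ],
    "C2H": [
        ("C", (0.0, 0.0, 1.43), -0.15),
        ("C", (0.0, 0.0, 2.63), -0.15),
        ("H", (0.0, 0.0, 3.69), 0.22),
    ],
    "CO": [
        ("C", (0.0, 0.0, 1.42), 0.35),
        ("O", (0.0, 1.05, 2.03), -0.40),
    ],
    "OH": [
        ("O", (0.0, 0.0, 1.36), -0.40),
        ("H", (0.91, 0.0, 1.66), 0.30),
    ],
    "COOH": [
        ("C", (0.0, 0.0, 1.50), 0.55),
        ("O", (1.05, 0.0, 2.13), -0.45),
        ("O", (-1.13, 0.0, 2.17), -0.45),
        ("H", (-1.03, 0.0, 3.13), 0.32),
    ],
    "SH": [
        ("S", (0.0, 0.0, 1.77), -0.20),
        ("H", (1.22, 0.0, 2.33), 0.12),
    ],
    "F": [("F", (0.0, 0.0, 1.35), -0.22)],
    "Cl": [("Cl", (0.0, 0.0, 1.74), -0.12)],
    "Br": [("Br", (0.0, 0.0, 1.90), -0.09)],
}

POSITION1_GROUPS = ("CH3", "H", "C2H5", "C2H3", "C2H", "CO")
POSITION5_GROUPS = ("OH", "COOH", "SH", "F", "Cl", "Br")

_GROUP_WORD = {
    "CH3": "Methyl", "H": "Hydrogen", "C2H5": "Ethyl", "C2H3": "Vinyl",
    "C2H": "Ethynyl", "CO": "Carbonyl", "OH": "Hydroxyl", "COOH": "Carboxyl",
    "SH": "Sulfur", "F": "Fluorine", "Cl": "Chlorine", "Br": "Bromine",
}
GROUP_DISPLAY_NAMES = _GROUP_WORD  # public alias for table-name joins


@dataclass
class DerivativeRecord:
    id: str
    name: str
    structure: Molecule | None
    pos1_group: str | None = None
    pos5_group: str | None = None
    predicted_cei: float | None = None
    relative_change_pct: float | None = None


def _exit_frame(mol: Molecule, placeholder_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Anchor position and rotation mapping local +z onto the exit vector."""
    coords = mol.coords
    place = coords[placeholder_idx]
    others = np.delete(np.arange(len(coords)), placeholder_idx)
    anchor_idx = others[np.argmin(np.linalg.norm(coords[others] - place, axis=1))]
    anchor = coords[anchor_idx]
    z = place - anchor
    norm = np.linalg.norm(z)
    if norm == 0:
        raise ValueError("degenerate exit vector at attachment point")
    z = z / norm
    # any orthonormal completion
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return anchor, np.column_stack([x, y, z])


def _substitute(mol: Molecule, position: str, group: str) -> Molecule:
    if position not in mol.labels:
        raise KeyError(f"template has no attachment label {position!r}")
    if group not in _FRAGMENTS:
        raise KeyError(f"unknown substituent group {group!r}")
    idx = mol.labels[position]
    anchor, rot = _exit_frame(mol, idx)

    keep = [i for i in range(len(mol.atoms)) if i != idx]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [replace(mol.atoms[i]) for i in keep]
    for element, offset, charge in _FRAGMENTS[group]:
        pos = anchor + rot @ np.asarray(offset)
        atoms.append(Atom.from_element(element, pos, charge))

    fmap = None
    if mol.framework_map is not None:
        fmap = {remap[i]: j for i, j in mol.framework_map.items() if i in remap}
    labels = {k: remap[v] for k, v in mol.labels.items() if v in remap}
    return Molecule(mol.id, atoms, fmap, labels)


def enumerate_derivatives(
    template: Molecule,
    pos1_groups=POSITION1_GROUPS,
    pos5_groups=POSITION5_GROUPS,
    template_name: str = "PAZ",
) -> list[DerivativeRecord]:
    """All single and double substitutions: |P1| + |P5| + |P1|*|P5| records.

    Ordering: position-1 singles, position-5 singles, then doubles with the
    position-1 group varying slowest.
    """
    records: list[DerivativeRecord] = []

    def add(name, structure, g1=None, g5=None):
        rid = f"Derivative-{len(records) + 1}"
        structure = replace_id(structure, rid)
        records.append(DerivativeRecord(rid, name, structure, g1, g5))

    def replace_id(m: Molecule, new_id: str) -> Molecule:
        return Molecule(new_id, m.atoms, m.framework_map, dict(m.labels))

    for g in pos1_groups:
        add(f"1-{_GROUP_WORD[g]}-{template_name}", _substitute(template, "pos1", g), g1=g)
    for g in pos5_groups:
        add(f"5-{_GROUP_WORD[g]}-{template_name}", _substitute(template, "pos5", g), g5=g)
    for g1 in pos1_groups:
        m1 = _substitute(template, "pos1", g1)
        for g5 in pos5_groups:
            add(
                f"1-{_GROUP_WORD[g1]}-5-{_GROUP_WORD[g5]}-{template_name}",
                _substitute(m1, "pos5", g5),
                g1=g1,
                g5=g5,
            )
    return records


def predict_derivative_cei(
    records: list[DerivativeRecord],
    model: PLSModel,
    table: DescriptorTable,
    template_cei: float,
    probe=CARBON_PROBE,
) -> list[DerivativeRecord]:
    """Run the full field -> descriptor -> PLS chain for each derivative and
    attach predicted CEI plus relative change versus the template."""
    blocks = [compute_field_block(r.structure, table.grid, probe) for r in records]
    X = table.transform(blocks)
    yhat = predict(model, X)
    out = []
    for rec, val in zip(records, yhat):
        out.append(
            replace(
                rec,
                predicted_cei=float(val),
                relative_change_pct=relative_change(float(val), template_cei),
            )
        )
    return out


def attach_changes(cei: pd.Series, template_cei: float) -> pd.Series:
    """Relative change (%) of each predicted CEI versus the template CEI.

    Used in table mode, when predicted CEIs come from an external model."""
    return pd.Series(
        [relative_change(float(v), template_cei) for v in cei],
        index=cei.index,
        name="relative_change_pct",
    )


def summarize_reduction_range(changes) -> tuple[float, float]:
    """(min |reduction|, max |reduction|) over entries with reduced CEI."""
    if isinstance(changes, list):  # records
        vals = np.array(
            [r.relative_change_pct for r in changes if r.relative_change_pct is not None]
        )
    else:
        vals = np.asarray(changes, dtype=float)
    reductions = -vals[vals < 0]
    if reductions.size == 0:
        raise ValueError("no records with reduced CEI")
    return float(reductions.min()), float(reductions.max())
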