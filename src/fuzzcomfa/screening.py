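"""Persistent-organic-pollutant screening cascade and averaged predictions.

Derivatives that lower the comprehensive ADR index are screened for
environmental friendliness on three externally predicted endpoints:

1. genotoxicity pLOEC (-log LOEC, mol/L): keep derivatives whose relative
   change versus the template is >= 0 (a derivative exactly matching the
   template passes);
2. photodegradability log t1/2: keep survivors whose relative change is
   strictly > 0;
3. bioconcentration log Kow: keep survivors whose relative change is < 0.

Relative changes are recomputed from the stored template row, never trusted
from input.  The cascade is monotone (survivor sets are nested) and
independent of row order.

The module also carries the averaged-prediction arithmetic used for
disinfection by-products (mean of several model predictions, change versus
the parent compound) and a pluggable linear-QSAR evaluator for
user-supplied literature models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fuzzy_eval import relative_change

__all__ = [
    "CascadeResult",
    "AveragedPrediction",
    "ENDPOINT_COLUMNS",
    "pop_screen",
    "average_prediction",
    "apply_linear_qsar",
    "range_summary",
]

ENDPOINT_COLUMNS = ("ploec", "log_t_half", "log_kow")


@dataclass
class CascadeResult:
    """Ordered survivor id lists per cascade stage, plus the recomputed
    relative-change table (percent, columns ``<endpoint>_change_pct``)."""

    stage1_genotox: list
    stage2_photodeg: list
    stage3_bioconc: list
    changes: pd.DataFrame

    @property
    def cardinalities(self) -> tuple[int, int, int]:
        return (len(self.stage1_genotox), len(self.stage2_photodeg),
                len(self.stage3_bioconc))


@dataclass
class AveragedPrediction:
    compound_id: str
    predictions: tuple
    pred_avg: float
    relative_change_pct: float | None = None


def pop_screen(table: pd.DataFrame, template_id: str = "PAZ") -> CascadeResult:
    """Run the three-stage screening cascade.

    ``table`` must be indexed by compound id and contain the columns
    ``ploec``, ``log_t_half`` and ``log_kow``, including a template row.
    """
    missing = [c for c in ENDPOINT_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"missing endpoint column(s): {missing}")
    if template_id not in table.index:
        raise KeyError(f"template row {template_id!r} absent from table")

    template = table.loc[template_id]
    rows = table.drop(index=template_id)
    changes = pd.DataFrame(index=rows.index)
    for col in ENDPOINT_COLUMNS:
        ref = float(template[col])
        changes[f"{col}_change_pct"] = [
            relative_change(float(v), ref) for v in rows[col]
        ]

    s1 = list(changes.index[changes["ploec_change_pct"] >= 0])
    s2 = [i for i in s1 if changes.at[i, "log_t_half_change_pct"] > 0]
    s3 = [i for i in s2 if changes.at[i, "log_kow_change_pct"] < 0]
    return CascadeResult(s1, s2, s3, changes)


def average_prediction(
    compound_id: str, predictions, parent_value: float | None = None
) -> AveragedPrediction:
    """Arithmetic mean of several model predictions for one compound, with
    relative change versus the parent when a parent value is given."""
    preds = tuple(float(p) for p in predictions)
    if not preds:
        raise ValueError("need at least one model prediction")
    avg = float(np.mean(preds))
    change = relative_change(avg, parent_value) if parent_value is not None else None
    return AveragedPrediction(compound_id, preds, avg, change)


def apply_linear_qsar(descriptors, coefficients, intercept: float = 0.0) -> float:
    """Evaluate a user-supplied linear QSAR: dot(descriptors, coefficients)
    + intercept, matched by label."""
    d = pd.Series(descriptors, dtype=float)
    c = pd.Series(coefficients, dtype=float)
    extra = set(c.index) - set(d.index)
    if extra:
        raise KeyError(f"coefficient labels without descriptors: {sorted(extra)}")
    return float((d[c.index] * c).sum() + intercept)


def range_summary(values) -> tuple[float, float]:
    """(min, max) over a set of relative changes (or any values)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value set")
    return float(arr.min()), float(arr.max())
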