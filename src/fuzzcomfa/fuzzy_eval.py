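"""Fuzzy comprehensive evaluation of multi-endpoint toxicity scores.

A panel of adverse-reaction endpoints is scored per compound (here: protein
docking scores against the GABA receptor, cyclooxygenase and the hERG
channel).  Each endpoint column is mapped to a [0, 1] membership value with a
large-scale (min–max) membership function, and the membership matrix ``R`` is
collapsed to a single comprehensive evaluation index (CEI) per compound with
a weighted-average fuzzy operator::

    r_ij = (c_ij - min_j c_ij) / (max_j c_ij - min_j c_ij)
    CEI_j = sum_i a_i * r_ij,          sum_i a_i = 1

The CEI is the response variable for the downstream 3D-QSAR model.  Scores
enter as a tidy table (rows = compounds, columns = endpoints), the field's
usual orientation; the algebra is identical to the endpoint-by-compound
matrix formulation.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateEndpointError",
    "membership_matrix",
    "composite_index",
    "relative_change",
    "evaluate_table",
    "normalize_weights",
    "round_display",
]

LARGER = "larger_is_better"
SMALLER = "smaller_is_better"


class DegenerateEndpointError(ValueError):
    """An endpoint column has no spread (max == min), so min-max
    membership is undefined for it."""


def _orientation_map(endpoints, orientation) -> dict[str, str]:
    if isinstance(orientation, str):
        orientation = {e: orientation for e in endpoints}
    bad = set(orientation.values()) - {LARGER, SMALLER}
    if bad:
        raise ValueError(f"unknown orientation(s): {sorted(bad)}")
    missing = [e for e in endpoints if e not in orientation]
    if missing:
        raise ValueError(f"no orientation given for endpoint(s): {missing}")
    return dict(orientation)


def membership_matrix(
    scores: pd.DataFrame,
    orientation: str | Mapping[str, str] = LARGER,
) -> pd.DataFrame:
    """Min-max membership values per endpoint column.

    Parameters
    ----------
    scores
        Compounds (rows) x endpoints (columns), all finite, >= 2 rows.
    orientation
        ``"larger_is_better"`` (higher raw score -> membership 1) or
        ``"smaller_is_better"`` (mirrored), either globally or as a
        per-endpoint mapping.

    Returns
    -------
    DataFrame of the same shape with every value in [0, 1]; within each
    endpoint the best compound maps to 1 and the worst to 0.
    """
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 compounds per endpoint")
    values = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite with no missing cells")
    omap = _orientation_map(scores.columns, orientation)

    out = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for col in scores.columns:
        c = scores[col].to_numpy(dtype=float)
        lo, hi = c.min(), c.max()
        if hi == lo:
            raise DegenerateEndpointError(
                f"endpoint {col!r} is degenerate: max == min == {hi}"
            )
        r = (c - lo) / (hi - lo)
        if omap[col] == SMALLER:
            r = 1.0 - r
        out[col] = r
    return out


def normalize_weights(weights, endpoints=None) -> pd.Series:
    """Coerce a weight mapping/sequence to a Series summing to 1 (1e-9)."""
    if isinstance(weights, Mapping):
        w = pd.Series(weights, dtype=float)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=endpoints)
    if endpoints is not None:
        missing = [e for e in endpoints if e not in w.index]
        if missing:
            raise ValueError(f"weights missing endpoint(s): {missing}")
        w = w.reindex(endpoints)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return w


def composite_index(membership: pd.DataFrame, weights) -> pd.Series:
    """Weighted-average aggregation ``CEI_j = sum_i a_i r_ij``.

    ``weights`` may be a mapping keyed by endpoint or a sequence in column
    order; it must be non-negative and sum to 1, which makes the CEI a convex
    combination bounded in [0, 1].
    """
    w = normalize_weights(weights, endpoints=list(membership.columns))
    cei = membership.to_numpy(dtype=float) @ w.to_numpy()
    return pd.Series(cei, index=membership.index, name="cei")


def relative_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("relative change undefined for zero reference")
    return 100.0 * (value - reference) / reference


def round_display(x, decimals: int = 3):
    """Round half away from zero, the convention used for printed tables
    (numpy/python banker's rounding differs on exact .5 ties)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    rounded = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if rounded.ndim == 0:
        return float(rounded)
    return rounded


def evaluate_table(
    scores: pd.DataFrame,
    weights,
    orientation: str | Mapping[str, str] = LARGER,
) -> pd.DataFrame:
    """One-call pipeline: membership + weighted aggregation.

    Returns a table with one ``r_<endpoint>`` column per endpoint, the
    full-precision ``cei`` and a 3-decimal ``cei_display`` column.
    """
    r = membership_matrix(scores, orientation)
    cei = composite_index(r, weights)
    out = r.rename(columns={c: f"r_{c}" for c in r.columns})
    out["cei"] = cei
    out["cei_display"] = round_display(cei.to_numpy(), 3)
    return out
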