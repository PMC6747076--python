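"""Consistency checks between the multi-factor index and single-endpoint models.

A derivative's CEI change can be attributed to each endpoint in proportion
to its weight: ``weighted_change = cei_change * a_i``.  An independent
single-endpoint model predicts the same derivative's raw endpoint score,
giving ``single_change = 100 * (derivative - template) / template``.  The
agreement between the two is reported as::

    relative_error = 100 * |weighted_change - single_change| / |weighted_change|

i.e. the discrepancy as a fraction of the weighted multi-factor change (the
convention that reproduces the printed comparison tables; a
``denominator="single"`` variant is provided).  Small relative errors for
the heavily weighted endpoints support the chosen weighting.

Also provides the residual table for observed-vs-predicted response values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fuzzy_eval import relative_change

__all__ = ["SingleFactorRecord", "single_factor_compare", "residual_table"]


@dataclass
class SingleFactorRecord:
    endpoint: str
    weight: float
    template_score: float
    derivative_score: float
    single_change_pct: float
    weighted_cei_change_pct: float
    relative_error_pct: float


def single_factor_compare(
    cei_change_pct: float,
    weight: float,
    single_score_template: float,
    single_score_derivative: float,
    endpoint: str = "",
    denominator: str = "weighted",
) -> SingleFactorRecord:
    """Compare a weight-attributed CEI change with a single-endpoint change.

    The comparison is scale-invariant in the raw scores: multiplying both
    endpoint scores by a positive constant changes nothing.
    """
    if not 0 < weight <= 1:
        raise ValueError("weight must be in (0, 1]")
    if single_score_template == 0:
        raise ZeroDivisionError("zero template score")
    single = relative_change(single_score_derivative, single_score_template)
    weighted = cei_change_pct * weight
    if denominator == "weighted":
        ref = weighted
    elif denominator == "single":
        ref = single
    else:
        raise ValueError("denominator must be 'weighted' or 'single'")
    if ref == 0:
        raise ZeroDivisionError("zero reference change for relative error")
    rel_err = 100.0 * abs(weighted - single) / abs(ref)
    return SingleFactorRecord(
        endpoint=endpoint,
        weight=weight,
        template_score=single_score_template,
        derivative_score=single_score_derivative,
        single_change_pct=single,
        weighted_cei_change_pct=weighted,
        relative_error_pct=rel_err,
    )


def residual_table(observed, predicted) -> pd.DataFrame:
    """Per-compound absolute percent residuals, 100*|pred - obs|/obs, with
    min/max recorded in ``DataFrame.attrs['residual_range']``."""
    obs = pd.Series(observed, dtype=float)
    pred = pd.Series(predicted, dtype=float)
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must align")
    if (obs == 0).any():
        raise ZeroDivisionError("zero observed value")
    pred.index = obs.index
    resid = 100.0 * (pred - obs).abs() / obs.abs()
    out = pd.DataFrame(
        {"observed": obs, "predicted": pred, "residual_pct": resid}
    )
    out.attrs["residual_range"] = (float(resid.min()), float(resid.max()))
    return out
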