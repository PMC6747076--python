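"""Partial least squares regression with the CoMFA validation-statistic suite.

The latent-variable regression itself is NIPALS PLS1 (scikit-learn's
``PLSRegression`` on mean-centered, unscaled data).  Everything a 3D-QSAR
practitioner reports around it is implemented here:

* leave-one-out cross-validation: ``q2 = 1 - PRESS / SS_tot`` with SS_tot
  taken about each training fold's mean (the SYBYL convention; a whole-set
  mean variant is available), and ``SEP = sqrt(PRESS / (N - n - 1))``;
* fitted statistics ``r2``, ``SEE = sqrt(SS_res / (N - n - 1))`` and the
  regression ``F = (SS_reg / n) / (SS_res / (N - n - 1))``;
* external validation ``Q2_ext = 1 - sum (y_i - yhat_i)^2 / sum (y_i -
  ybar_train)^2`` over a held-out test set, plus ``r2_pred``, the squared
  Pearson correlation of observed vs predicted test values;
* progressive Y-scrambling: partially permute the response, track q2 and
  SDEP against the correlation r2_yy' between true and perturbed response;
  report cSDEP at a reference correlation and the slope dq2/dr2_yy';
* per-field contribution percentages from |coefficient| * column sd.

Component counts are capped at min(rows - 1, columns); the default selection
policy is argmax q2 with ties broken toward fewer components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PLSModel",
    "ModelStats",
    "SplitSpec",
    "fit_pls",
    "predict",
    "loo_crossvalidate",
    "select_components",
    "fit_statistics",
    "external_q2",
    "progressive_scrambling",
    "field_contributions",
    "make_split",
    "save_model",
    "load_model",
]

DEFAULT_COMPONENT_CAP = 10
SCRAMBLING_REFERENCE_R2 = 0.85


@dataclass
class PLSModel:
    n_components: int
    coefficients: pd.Series  # on original (centered) columns
    x_mean: pd.Series
    y_mean: float
    columns: pd.Index
    field_labels: pd.Series | None = None  # column -> "steric"/"electrostatic"
    x_sd: pd.Series | None = None  # training column sd (contour/contribution use)
    warnings_: list[str] | None = None


@dataclass
class ModelStats:
    q2: float
    n: int
    r2: float
    see: float
    f_value: float
    sep: float | None = None
    r2_pred: float | None = None
    q2_ext: float | None = None
    csdep: float | None = None
    dq2_dr2yy: float | None = None
    steric_contribution_pct: float | None = None
    electrostatic_contribution_pct: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    seed: int


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _as_series(y, index) -> pd.Series:
    if isinstance(y, pd.Series):
        return y.astype(float)
    return pd.Series(np.asarray(y, dtype=float), index=index)


def fit_pls(X, y, n_components: int, field_labels: pd.Series | None = None) -> PLSModel:
    """Fit a PLS1 model on mean-centered data.

    ``n_components`` is clipped (with a recorded warning) to the largest
    value the data can support, min(rows - 1, columns, rank).
    """
    X = _as_frame(X)
    y = _as_series(y, X.index)
    n_rows, n_cols = X.shape
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    notes: list[str] = []
    Xc = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xc - Xc.mean(axis=0))
    cap = max(1, min(n_rows - 1, n_cols, rank))
    if n_components > cap:
        notes.append(f"n_components clipped from {n_components} to {cap}")
        n_components = cap

    if np.allclose(y.to_numpy(), y.mean()):
        # constant response: PLS weights are undefined; the least-squares
        # answer is the zero model predicting ybar
        coef = pd.Series(np.zeros(n_cols), index=X.columns)
    else:
        pls = PLSRegression(n_components=n_components, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xc, y.to_numpy())
        coef = pd.Series(np.ravel(pls.coef_), index=X.columns)

    return PLSModel(
        n_components=n_components,
        coefficients=coef,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        columns=X.columns,
        field_labels=field_labels,
        x_sd=X.std(axis=0, ddof=1),
        warnings_=notes,
    )


def predict(model: PLSModel, X_new) -> pd.Series:
    """Deterministic linear map: yhat = ybar + (x - xbar) . b."""
    X_new = _as_frame(X_new)
    if list(X_new.columns) != list(model.columns):
        raise ValueError("column metadata mismatch between model and input")
    centered = X_new.to_numpy(dtype=float) - model.x_mean.to_numpy()
    yhat = model.y_mean + centered @ model.coefficients.to_numpy()
    return pd.Series(yhat, index=X_new.index, name="predicted")


def loo_crossvalidate(
    X, y, max_components: int = DEFAULT_COMPONENT_CAP, sstot: str = "fold_mean"
) -> pd.DataFrame:
    """Leave-one-out q2 and SEP for 1..max_components latent variables.

    ``sstot="fold_mean"`` computes the total sum of squares about each
    training fold's mean (SYBYL convention); ``"overall_mean"`` uses the
    whole-set mean.
    """
    X = _as_frame(X)
    y = _as_series(y, X.index)
    n_rows = len(X)
    if n_rows < 3:
        raise ValueError("need at least 3 rows for leave-one-out")
    if sstot not in ("fold_mean", "overall_mean"):
        raise ValueError("sstot must be 'fold_mean' or 'overall_mean'")
    cap = min(max_components, n_rows - 2, X.shape[1])

    rows = [
        dict(n_components=n, **_loo_once(X, y, n, sstot)) for n in range(1, cap + 1)
    ]
    return pd.DataFrame(rows).set_index("n_components")


def _loo_once(X: pd.DataFrame, y: pd.Series, n: int, sstot: str = "fold_mean") -> dict:
    n_rows = len(X)
    press = 0.0
    ss_tot = 0.0
    for i in range(n_rows):
        mask = np.ones(n_rows, dtype=bool)
        mask[i] = False
        model = fit_pls(X.iloc[mask], y.iloc[mask], n)
        pred = predict(model, X.iloc[[i]]).iloc[0]
        press += (y.iloc[i] - pred) ** 2
        ref = y.iloc[mask].mean() if sstot == "fold_mean" else y.mean()
        ss_tot += (y.iloc[i] - ref) ** 2
    q2 = 1.0 - press / ss_tot
    dof = n_rows - n - 1
    sep = float(np.sqrt(press / dof)) if dof > 0 else np.nan
    return {"q2": float(q2), "press": float(press), "sep": sep}


def select_components(
    q2_curve: pd.Series, policy: str = "max", tolerance: float = 0.0,
    cap: int = DEFAULT_COMPONENT_CAP,
) -> int:
    """Pick the component count from a q2-vs-n curve.

    ``"max"``: argmax q2, ties toward fewer components. ``"parsimony"``:
    smallest n with q2 within ``tolerance`` of the maximum.
    """
    if isinstance(q2_curve, pd.DataFrame):
        q2_curve = q2_curve["q2"]
    q2_curve = q2_curve[q2_curve.index <= cap]
    if q2_curve.empty:
        raise ValueError("empty q2 curve")
    best = q2_curve.max()
    if policy == "max":
        return int(q2_curve.idxmax())  # idxmax returns first (smallest n) on ties
    if policy == "parsimony":
        ok = q2_curve[q2_curve >= best - tolerance]
        return int(ok.index.min())
    raise ValueError(f"unknown policy {policy!r}")


def fit_statistics(model: PLSModel, X, y) -> tuple[float, float, float]:
    """Training r2, SEE and F for a fitted model.

    SEE and F use N - n - 1 residual degrees of freedom, n = number of
    latent components.
    """
    X = _as_frame(X)
    y = _as_series(y, X.index)
    n_rows = len(y)
    n = model.n_components
    if n_rows <= n + 1:
        raise ValueError(f"N={n_rows} leaves no residual degrees of freedom for n={n}")
    yhat = predict(model, X)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_reg = ss_tot - ss_res
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    see = float(np.sqrt(ss_res / (n_rows - n - 1)))
    f_value = (ss_reg / n) / (ss_res / (n_rows - n - 1)) if ss_res > 0 else np.inf
    return r2, see, f_value


def external_q2(y_test_obs, y_test_pred, y_train_mean: float) -> tuple[float, float]:
    """External predictive statistics over a held-out test set.

    Returns ``(Q2_ext, r2_pred)`` where ``Q2_ext = 1 - sum (y_i - yhat_i)^2 /
    sum (y_i - ybar_train)^2`` and ``r2_pred`` is the squared Pearson
    correlation between observed and predicted test values.
    """
    obs = np.asarray(y_test_obs, dtype=float)
    pred = np.asarray(y_test_pred, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 test compounds")
    denom = float(((obs - y_train_mean) ** 2).sum())
    if denom == 0:
        raise ValueError("zero test variance about the training mean")
    q2_ext = 1.0 - float(((obs - pred) ** 2).sum()) / denom
    if np.std(obs) == 0 or np.std(pred) == 0:
        r2_pred = 0.0
    else:
        r2_pred = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return q2_ext, r2_pred


def _partial_scramble(y: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Variance-preserving partial scramble: blend the centered response
    with a fully permuted copy, y' = mu + sqrt(1-t^2)*(y-mu) + t*perm(y-mu).

    strength t = 0 returns y unchanged; t = 1 is a full permutation.  The
    blend keeps the response variance constant across the ladder so q2
    changes reflect lost y-structure, not a shrinking signal scale.
    """
    if strength == 0:
        return y.copy()
    mu = y.mean()
    yc = y - mu
    perm = yc[rng.permutation(len(yc))]
    return mu + np.sqrt(1.0 - strength**2) * yc + strength * perm


def progressive_scrambling(
    X,
    y,
    n_components: int,
    reps: int = 10,
    seed: int = 0,
    levels: int = 10,
    reference_r2: float = SCRAMBLING_REFERENCE_R2,
) -> tuple[float, float, pd.DataFrame]:
    """Progressive Y-scrambling stability analysis.

    For a ladder of perturbation strengths the response is partially
    permuted; each perturbed response is re-cross-validated (LOO at
    ``n_components``).  Returns ``(cSDEP, dq2_dr2yy, detail)`` where cSDEP is
    the SDEP interpolated at ``reference_r2`` correlation between true and
    perturbed response, and dq2_dr2yy is the least-squares slope of q2
    against r2_yy'.  Fully seeded and deterministic.
    """
    if reps < 10:
        raise ValueError("need reps >= 10 for a stable scrambling estimate")
    X = _as_frame(X)
    y = _as_series(y, X.index)
    rng = np.random.default_rng(seed)
    yv = y.to_numpy()

    records = []
    for lvl in range(levels + 1):
        fraction = lvl / levels
        n_draws = 1 if lvl == 0 else reps
        for _ in range(n_draws):
            yp = _partial_scramble(yv, fraction, rng)
            if np.std(yp) == 0 or np.std(yv) == 0:
                r2yy = 1.0
            else:
                r2yy = float(np.corrcoef(yv, yp)[0, 1] ** 2)
            n_eff = min(n_components, len(X) - 2, X.shape[1])
            res = _loo_once(X, pd.Series(yp, index=y.index), n_eff)
            records.append({"fraction": fraction, "r2_yy": r2yy,
                            "q2": res["q2"], "sdep": res["sep"]})
    detail = pd.DataFrame(records)

    # SDEP at the reference correlation: linear interpolation on the
    # level-averaged curve, ordered by r2_yy'
    curve = detail.groupby("fraction")[["r2_yy", "sdep", "q2"]].mean()
    order = np.argsort(curve["r2_yy"].to_numpy())
    csdep = float(np.interp(reference_r2,
                            curve["r2_yy"].to_numpy()[order],
                            curve["sdep"].to_numpy()[order]))
    slope = float(np.polyfit(detail["r2_yy"], detail["q2"], 1)[0])
    return csdep, slope, detail


def field_contributions(model: PLSModel, field_labels: pd.Series | None = None) -> dict[str, float]:
    """Percent contribution per field block: sum of |coef| * column sd,
    normalized to 100."""
    labels = field_labels if field_labels is not None else model.field_labels
    if labels is None:
        raise ValueError("no field labels available")
    if model.x_sd is None:
        raise ValueError("model lacks training column sd")
    weight = (model.coefficients.abs() * model.x_sd).groupby(labels).sum()
    total = weight.sum()
    if total == 0:
        # zero model: split evenly over present blocks
        return {k: 100.0 / len(weight) for k in weight.index}
    return {k: float(100.0 * v / total) for k, v in weight.items()}


def save_model(model: PLSModel, path) -> None:
    """Serialize a fitted model to a self-describing JSON container.

    Arrays are stored as lists keyed by column label, so the file is
    human-inspectable and diff-friendly.
    """
    import json

    payload = {
        "format": "fuzzcomfa-pls/1",
        "n_components": model.n_components,
        "y_mean": model.y_mean,
        "columns": list(map(str, model.columns)),
        "coefficients": model.coefficients.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_sd": None if model.x_sd is None else model.x_sd.tolist(),
        "field_labels": None if model.field_labels is None
        else list(model.field_labels),
        "warnings": model.warnings_ or [],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> PLSModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "fuzzcomfa-pls/1":
        raise ValueError(f"not a fuzzcomfa PLS model file: {path}")
    cols = pd.Index(payload["columns"])
    return PLSModel(
        n_components=payload["n_components"],
        coefficients=pd.Series(payload["coefficients"], index=cols),
        x_mean=pd.Series(payload["x_mean"], index=cols),
        y_mean=payload["y_mean"],
        columns=cols,
        field_labels=None if payload["field_labels"] is None
        else pd.Series(payload["field_labels"], index=cols),
        x_sd=None if payload["x_sd"] is None
        else pd.Series(payload["x_sd"], index=cols),
        warnings_=payload["warnings"],
    )


def make_split(
    ids, train_size: int = 22, seed: int = 0, template_id=None
) -> SplitSpec:
    """Seeded uniform train/test split (default 22 train of 29, ~3:1).

    If ``template_id`` is given, the template molecule is guaranteed to
    appear in both roles: it is placed in the training set and additionally
    duplicated into the test evaluation set.
    """
    ids = list(ids)
    if not 0 < train_size < len(ids):
        raise ValueError("train_size must be in (0, N)")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    train = perm[:train_size]
    test = perm[train_size:]
    if template_id is not None:
        if template_id not in ids:
            raise ValueError(f"template {template_id!r} not among ids")
        if template_id not in train:
            # swap the template into training for a random training molecule
            swap = train[0]
            train[0] = template_id
            test[test.index(template_id)] = swap
        if template_id not in test:
            # duplicate into the test evaluation set
            test.append(template_id)
    return SplitSpec(tuple(train), tuple(test), seed)
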