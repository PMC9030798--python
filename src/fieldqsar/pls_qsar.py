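"""Partial least squares regression for field descriptors.

PLS compresses thousands of correlated grid columns into a few latent
variables that maximize covariance with activity.  The module wraps a
NIPALS-style fit (scikit-learn's ``PLSRegression``) behind a small model
container, and layers the QSAR statistics on top:

* leave-one-out cross-validation: per-component q², the optimal number of
  components (ONC, the argmax of q² with ties broken toward fewer
  components), and SEP;
* the no-validation fit at the ONC: r², SEE and the F statistic;
* bootstrap r² (mean ± SD over resampled refits);
* StDev*Coeff contour values (coefficient × column SD mapped back onto the
  grid) and per-field percent contributions.

The per-component LOO path exploits the sequential structure of NIPALS:
truncating the weight/loading sequence of a ``c_max``-component fit yields
exactly the ``c``-component model, so one fit per left-out compound covers
every component count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .fields import DescriptorMatrix, GridSpec

logger = logging.getLogger(__name__)


@dataclass
class PlsModel:
    """Latent-variable regression state for a fitted PLS model."""

    n_components: int
    coefficients: np.ndarray        # per descriptor column, raw-X scale
    intercept: float
    x_weights: np.ndarray           # (m, c)
    x_loadings: np.ndarray          # (m, c)
    x_rotations: np.ndarray         # (m, c): scores = (X − x_mean) @ rotations
    x_scores: np.ndarray            # (n, c) training scores
    y_loadings: np.ndarray          # (c,)
    x_mean: np.ndarray
    y_mean: float
    training_ids: list[str]
    column_meta: list[tuple[int, str]] | None = None
    grid: GridSpec | None = None

    @property
    def n_train(self) -> int:
        return len(self.training_ids)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) @ self.x_rotations


@dataclass
class CvResult:
    """Internal PLS statistics: LOO cross-validation plus the full-data fit."""

    q2: float
    onc: int
    sep: float
    r2: float
    see: float
    f_value: float
    per_component_q2: np.ndarray
    bs_r2: float | None = None
    bs_sd: float | None = None


def _as_xy(X, y=None):
    ids = None
    meta = grid = None
    if isinstance(X, DescriptorMatrix):
        ids, meta, grid = X.ids, X.column_meta, X.grid
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y have mismatched lengths")
    return X, y, ids, meta, grid


def _fit_raw(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, y)
    return pls


def fit_pls(X, y, n_components: int) -> PlsModel:
    """Fit a PLS model with ``n_components`` latent variables.

    If the data cannot support the requested number of components the fit
    proceeds with the achievable count and a warning is logged.
    """
    X, y, ids, meta, grid = _as_xy(X, y)
    n, m = X.shape
    if n < n_components + 2:
        raise ValueError(f"need at least n_components+2 samples ({n_components + 2}), got {n}")
    cap = min(n - 1, m)
    if n_components > cap:
        logger.warning("requested %d components but only %d achievable; fitting %d",
                       n_components, cap, cap)
        n_components = cap
    pls = _fit_raw(X, y, n_components)
    coef = np.asarray(pls.coef_).reshape(-1)
    x_mean = pls._x_mean if hasattr(pls, "_x_mean") else X.mean(axis=0)
    y_mean = float(np.mean(y))
    intercept = y_mean - float(x_mean @ coef)
    return PlsModel(
        n_components=n_components,
        coefficients=coef,
        intercept=intercept,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        x_rotations=pls.x_rotations_,
        x_scores=pls.x_scores_,
        y_loadings=np.asarray(pls.y_loadings_).reshape(-1),
        x_mean=np.asarray(x_mean, float),
        y_mean=y_mean,
        training_ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        column_meta=meta,
        grid=grid,
    )


def predict(model: PlsModel, X_new) -> np.ndarray:
    """Predict activity: ŷ = X·coefficients + intercept."""
    X, _, _, meta, _ = _as_xy(X_new)
    if meta is not None and model.column_meta is not None and meta != model.column_meta:
        for j, (a, b) in enumerate(zip(meta, model.column_meta)):
            if a != b:
                raise ValueError(f"descriptor column mismatch at column {j}: {a} != {b}")
        raise ValueError("descriptor column count mismatch "
                         f"({len(meta)} vs {len(model.column_meta)})")
    if X.shape[1] != len(model.coefficients):
        raise ValueError(f"expected {len(model.coefficients)} columns, got {X.shape[1]}")
    return X @ model.coefficients + model.intercept


def _loo_component_predictions(X: np.ndarray, y: np.ndarray,
                               max_components: int) -> np.ndarray:
    """LOO predictions, shape (n, max_components): column c-1 = c-component model.

    One c_max fit per left-out sample; truncated rotations give every smaller
    model exactly (NIPALS weight/loading triangularity).
    """
    n = len(y)
    preds = np.empty((n, max_components))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        pls = _fit_raw(Xt, yt, max_components)
        x_mean = Xt.mean(axis=0)
        t_new = (X[i] - x_mean) @ pls.x_rotations_          # (c_max,)
        q = np.asarray(pls.y_loadings_).reshape(-1)          # (c_max,)
        preds[i] = yt.mean() + np.cumsum(t_new * q)
    return preds


def loo_validate(X, y, max_components: int = 10) -> CvResult:
    """Leave-one-out validation over 1..max_components latent variables.

    q²(c) = 1 − PRESS(c)/SS_total;  ONC = argmax_c q² (ties → fewer
    components);  SEP = √(PRESS/(n−c−1)) at the ONC; the full-data refit at
    the ONC supplies r², SEE = √(RSS/(n−c−1)) and
    F = (r²/c) / ((1−r²)/(n−c−1)).
    """
    X, y, ids, meta, grid = _as_xy(X, y)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 compounds for LOO validation, got {n}")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("constant response: q2 undefined")
    cmax = min(max_components, n - 2, X.shape[1])
    preds = _loo_component_predictions(X, y, cmax)
    press = np.sum((y[:, None] - preds) ** 2, axis=0)
    q2 = 1.0 - press / ss_total
    onc = int(np.argmax(q2)) + 1
    sep = float(np.sqrt(press[onc - 1] / (n - onc - 1)))

    model = fit_pls(X, y, onc)
    resid = y - (X @ model.coefficients + model.intercept)
    rss = float(np.sum(resid ** 2))
    r2 = 1.0 - rss / ss_total
    see = float(np.sqrt(rss / (n - onc - 1)))
    f_value = (r2 / onc) / ((1.0 - r2) / (n - onc - 1))
    return CvResult(q2=float(q2[onc - 1]), onc=onc, sep=sep, r2=r2, see=see,
                    f_value=f_value, per_component_q2=q2)


def bootstrap_r2(X, y, onc: int, n_boot: int = 100,
                 seed: int = 0) -> tuple[float, float]:
    """Bootstrap the non-validated r²: resample compounds, refit, report mean ± SD."""
    if n_boot < 10:
        logger.warning("n_boot=%d is small; bootstrap statistics will be noisy", n_boot)
    X, y, *_ = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    r2s = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        ss = np.sum((yb - yb.mean()) ** 2)
        if ss == 0:
            continue
        try:
            m = fit_pls(X[idx], yb, onc)
        except Exception:
            continue
        resid = yb - (X[idx] @ m.coefficients + m.intercept)
        r2s.append(1.0 - float(np.sum(resid ** 2)) / ss)
    r2s = np.asarray(r2s)
    return float(r2s.mean()), float(r2s.std(ddof=1))


def stdev_coeff_field(model: PlsModel, X) -> pd.DataFrame:
    """StDev*Coeff contour values per grid point and field.

    value(column) = coefficient(column) × SD of the column over the training
    set; exported with the grid coordinates of each point for visualization.
    """
    if model.column_meta is None:
        raise ValueError("model carries no column metadata; fit from a DescriptorMatrix")
    Xv, _, _, _, _ = _as_xy(X)
    sd = Xv.std(axis=0, ddof=1)
    values = model.coefficients * sd
    grid = model.grid
    pts = grid.points() if grid is not None else None
    rows = []
    for j, (pt, label) in enumerate(model.column_meta):
        row = {"point": pt, "field": label, "value": values[j]}
        if pts is not None:
            row.update(x=pts[pt, 0], y=pts[pt, 1], z=pts[pt, 2])
        rows.append(row)
    return pd.DataFrame(rows)


def field_contributions(model: PlsModel, X) -> dict[str, float]:
    """Percent contribution of each field block: Σ|β_j|·SD_j within block,
    normalized to sum to 100."""
    if model.column_meta is None:
        raise ValueError("model carries no column metadata")
    Xv, _, _, _, _ = _as_xy(X)
    sd = Xv.std(axis=0, ddof=1)
    weight = np.abs(model.coefficients) * sd
    labels = np.array([m[1] for m in model.column_meta])
    total = weight.sum()
    if total == 0:
        raise ValueError("all contour weights are zero")
    return {label: float(100.0 * weight[labels == label].sum() / total)
            for label in dict.fromkeys(labels)}


def save_model(model: PlsModel, path) -> None:
    """Persist a fitted model as JSON (arrays as lists)."""
    import json

    doc = {
        "n_components": model.n_components,
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "x_rotations": model.x_rotations.tolist(),
        "x_scores": model.x_scores.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "training_ids": model.training_ids,
        "column_meta": model.column_meta,
        "grid": None if model.grid is None else {
            "origin": list(model.grid.origin), "spacing": model.grid.spacing,
            "dims": list(model.grid.dims)},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> PlsModel:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    grid = None
    if doc["grid"] is not None:
        g = doc["grid"]
        grid = GridSpec(tuple(g["origin"]), g["spacing"], tuple(g["dims"]))
    meta = None
    if doc["column_meta"] is not None:
        meta = [(int(pt), str(label)) for pt, label in doc["column_meta"]]
    return PlsModel(
        n_components=doc["n_components"],
        coefficients=np.asarray(doc["coefficients"]),
        intercept=doc["intercept"],
        x_weights=np.asarray(doc["x_weights"]),
        x_loadings=np.asarray(doc["x_loadings"]),
        x_rotations=np.asarray(doc["x_rotations"]),
        x_scores=np.asarray(doc["x_scores"]),
        y_loadings=np.asarray(doc["y_loadings"]),
        x_mean=np.asarray(doc["x_mean"]),
        y_mean=doc["y_mean"],
        training_ids=doc["training_ids"],
        column_meta=meta,
        grid=grid,
    )


def write_contours(contours: pd.DataFrame, path) -> None:
    """Delimited (x,y,z,field,value) point list for external visualization."""
    cols = [c for c in ("x", "y", "z", "field", "value") if c in contours.columns]
    contours[cols].to_csv(path, index=False)


def write_dx(contours: pd.DataFrame, grid: GridSpec, field_label: str, path) -> None:
    """OpenDX-style scalar grid export of one field's StDev*Coeff values."""
    sel = contours[contours["field"] == field_label]
    values = np.zeros(grid.n_points)
    values[sel["point"].to_numpy(int)] = sel["value"].to_numpy(float)
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    d = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0 0", f"delta 0 {d:.6f} 0", f"delta 0 0 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_points} data follows",
    ]
    vals = values.reshape(grid.dims).ravel(order="C")
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "field" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
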