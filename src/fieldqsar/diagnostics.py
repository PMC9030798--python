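"""Applicability domain (Williams plot) and progressive response scrambling.

Leverage is computed in the fitted model's latent-score space rather than in
raw descriptor space: a field matrix has thousands of columns for ~10² of
compounds, so the descriptor-space hat matrix is degenerate, while the score
space carries exactly the dimensions the model actually uses.  For compound i
with score vector t_i and training score matrix T,

    h_i = 1/n + t_iᵀ (TᵀT)⁻¹ t_i ,

and the training leverages sum to c + 1 for a c-component model.  The warning
leverage is h* = 3(p+1)/n with p the number of descriptor field blocks — the
convention of the emulated field-QSAR toolchain; the textbook parameter-count
convention is available via ``convention="parameters"``.

Progressive scrambling perturbs the response in a graded way: compounds are
sorted by activity and cut into b contiguous bins, and activities are permuted
within bins.  Many bins ⇒ mild perturbation (r²_yy′ → 1), one bin ⇒ full
scrambling (r²_yy′ ≈ 0).  Quadratics of the scrambled LOO q² and SDEP against
r²_yy′ are evaluated at the critical perturbation r²_yy′ = 0.85, yielding the
reported Q², cSDEP and the sensitivity slope dq²/dr²_yy′.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls_qsar import PlsModel, _as_xy, _loo_component_predictions

logger = logging.getLogger(__name__)


@dataclass
class AdResult:
    """Williams-plot data: leverages, standardized residuals and flags."""

    ids: list[str]
    leverages: np.ndarray
    standardized_residuals: np.ndarray
    h_star: float
    roles: list[str]                     # "train" / "test" per compound
    outlier_flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.outlier_flags = (self.leverages > self.h_star) | \
                             (np.abs(self.standardized_residuals) > 3.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": self.ids, "role": self.roles,
            "leverage": self.leverages,
            "std_residual": self.standardized_residuals,
            "h_star": self.h_star, "outlier": self.outlier_flags,
        })


@dataclass
class ScramblingCurve:
    """Progressive-scrambling summary per component count."""

    points: pd.DataFrame                  # columns: components, bins, rep, r2yy, q2s, sdeps
    summary: pd.DataFrame                 # columns: components, Q2, cSDEP, slope
    critical_point: float = 0.85


def leverages(model: PlsModel, X_query) -> np.ndarray:
    """Score-space leverages h_i = 1/n + t_iᵀ(TᵀT)⁻¹t_i for query compounds."""
    Xq, _, _, meta, _ = _as_xy(X_query)
    if meta is not None and model.column_meta is not None and meta != model.column_meta:
        raise ValueError("descriptor columns do not match the fitted model")
    T = model.x_scores
    G = T.T @ T
    if np.linalg.cond(G) > 1e12:
        raise np.linalg.LinAlgError("singular score covariance; reduce components")
    t = model.scores(Xq)
    h = 1.0 / model.n_train + np.einsum("ij,jk,ik->i", t, np.linalg.inv(G), t)
    return h


def warning_leverage(n_train: int, n_field_blocks: int,
                     convention: str = "field_blocks",
                     n_components: int | None = None) -> float:
    """Warning leverage h* = 3(p+1)/n.

    With ``convention="field_blocks"`` (default) p counts descriptor field
    blocks (2 for steric+electrostatic, up to 5 with all similarity fields);
    with ``convention="parameters"`` p is the latent-variable count of the
    model (pass ``n_components``).
    """
    if convention == "field_blocks":
        p = n_field_blocks
    elif convention == "parameters":
        if n_components is None:
            raise ValueError("parameters convention requires n_components")
        p = n_components
    else:
        raise ValueError(f"unknown h* convention {convention!r}")
    if n_train <= 3 * (p + 1):
        logger.warning("n_train=%d is small for p=%d; h* exceeds 1/3", n_train, p)
    return 3.0 * (p + 1) / n_train


def williams_data(model: PlsModel, X_train, y_train, h_star: float,
                  X_test=None, y_test=None) -> AdResult:
    """Leverage vs standardized-residual table for the Williams plot.

    Standardized residuals are fitted residuals divided by the RMSE of the
    respective (train or test) set.
    """
    from .pls_qsar import predict

    def block(X, y, role):
        Xv, yv, ids, _, _ = _as_xy(X, y)
        resid = yv - predict(model, X)
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        if rmse < 1e-10:
            raise ValueError(f"zero RMSE on the {role} set: standardized "
                             "residuals are undefined")
        h = leverages(model, X)
        ids = ids if ids is not None else [f"{role}{i}" for i in range(len(yv))]
        return ids, h, resid / rmse, [role] * len(yv)

    ids, h, sr, roles = block(X_train, y_train, "train")
    if X_test is not None:
        ids2, h2, sr2, roles2 = block(X_test, y_test, "test")
        ids, h = ids + ids2, np.concatenate([h, h2])
        sr, roles = np.concatenate([sr, sr2]), roles + roles2
    return AdResult(ids, h, sr, h_star, roles)


def _scramble_within_bins(y: np.ndarray, n_bins: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Permute activities within contiguous bins of the activity-sorted order."""
    order = np.argsort(y, kind="stable")
    y_s = y.copy()
    for chunk in np.array_split(order, n_bins):
        y_s[chunk] = y[chunk][rng.permutation(len(chunk))]
    return y_s


def progressive_scrambling(X, y, components, bins_range=range(2, 11),
                           n_reps: int = 20, seed: int = 0,
                           critical_point: float = 0.85) -> ScramblingCurve:
    """Scrambling robustness test over one or more component counts.

    For each bin count b and repetition: scramble y within activity bins,
    record r²_yy′ (squared correlation of original vs scrambled response) and
    the scrambled model's LOO q² and SDEP at each requested component count;
    then fit quadratics of q²_s and SDEP_s against r²_yy′ and report their
    values at the critical point plus the slope dq²/dr²_yy′ there.
    """
    Xv, yv, *_ = _as_xy(X, y)
    n = len(yv)
    comps = [components] if np.isscalar(components) else list(components)
    cmax = max(comps)
    rng = np.random.default_rng(seed)
    rows = []
    for b in bins_range:
        if b > n:
            logger.warning("bin count %d exceeds n=%d; skipped", b, n)
            continue
        for rep in range(n_reps):
            y_s = _scramble_within_bins(yv, b, rng)
            if np.ptp(y_s) == 0:
                continue
            r = np.corrcoef(yv, y_s)[0, 1]
            r2yy = r * r
            preds = _loo_component_predictions(Xv, y_s, min(cmax, n - 2, Xv.shape[1]))
            press = np.sum((y_s[:, None] - preds) ** 2, axis=0)
            ss = np.sum((y_s - y_s.mean()) ** 2)
            for c in comps:
                cc = min(c, preds.shape[1])
                rows.append({
                    "components": c, "bins": b, "rep": rep, "r2yy": r2yy,
                    "q2s": 1.0 - press[cc - 1] / ss,
                    "sdeps": float(np.sqrt(press[cc - 1] / (n - cc - 1))),
                })
    points = pd.DataFrame(rows)
    if points.empty:
        raise ValueError("no scrambling repetitions could be evaluated")

    summary_rows = []
    for c in comps:
        sub = points[points["components"] == c]
        x = sub["r2yy"].to_numpy()
        if len(sub) < 3 or np.ptp(x) == 0:
            logger.warning("too little r²_yy′ spread for components=%d; skipped", c)
            continue
        deg = 2 if len(np.unique(x)) > 2 else 1
        pq = np.polyfit(x, sub["q2s"].to_numpy(), deg)
        ps = np.polyfit(x, sub["sdeps"].to_numpy(), deg)
        summary_rows.append({
            "components": c,
            "Q2": float(np.polyval(pq, critical_point)),
            "cSDEP": float(np.polyval(ps, critical_point)),
            "slope": float(np.polyval(np.polyder(pq), critical_point)),
            "fit_residual_q2": float(np.sqrt(np.mean(
                (np.polyval(pq, x) - sub["q2s"]) ** 2))),
        })
    return ScramblingCurve(points, pd.DataFrame(summary_rows), critical_point)
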