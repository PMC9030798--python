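"""Train/test splitting and the QSAR internal/external validation battery.

External predictivity is screened with the through-origin regression
criteria of Golbraikh & Tropsha (slopes k, k′ and through-origin
determination coefficients r0², r′0²), Roy's rm² family
(rm² = r²(1 − √(r² − r0²))), the Q_F1/Q_F2/Q_F3 external q² variants of
Gramatica/Todeschini, and Lin's concordance correlation coefficient.
Error statistics follow the conventions common in the 3D-QSAR literature:
χ² = Σe²/|ŷ| and MAE reported as the magnitude of the mean signed error
(a bias measure; the conventional mean-absolute-error is available as
``mean_abs_error``).

Splitting is activity-stratified: compounds are binned into high/medium/low
terciles, each stratum is shuffled and dealt into four folds, and fold k of
every stratum forms the test set of SET k, giving four train/test pairs of
~3:1 ratio that jointly cover every compound exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import MoleculeDataset
from .pls_qsar import CvResult

logger = logging.getLogger(__name__)

SET_NAMES = ("SET-A", "SET-B", "SET-C", "SET-D")


@dataclass
class SplitScheme:
    """Stratified 4-fold split: per-compound (stratum, fold) assignments."""

    n_strata: int
    n_folds: int
    seed: int
    assignments: dict[str, tuple[int, int]]

    def sets(self) -> list[tuple[list[str], list[str]]]:
        """(train_ids, test_ids) per SET; test of SET k = fold k of each stratum."""
        out = []
        for k in range(self.n_folds):
            test = [cid for cid, (_, f) in self.assignments.items() if f == k]
            train = [cid for cid, (_, f) in self.assignments.items() if f != k]
            out.append((train, test))
        return out


@dataclass
class MetricReport:
    """The external/internal validation metric battery for one model."""

    chi2: float = np.nan
    rmse: float = np.nan
    mae: float = np.nan
    rss: float = np.nan
    r2: float = np.nan
    k: float = np.nan
    k_prime: float = np.nan
    r0_2: float = np.nan
    r0p_2: float = np.nan
    abs_r0_diff: float = np.nan
    rel_r0_gap: float = np.nan
    rel_r0p_gap: float = np.nan
    rm2: float = np.nan
    rm2_prime: float = np.nan
    rm2_bar: float = np.nan
    delta_rm2: float = np.nan
    r_pred2: float = np.nan
    qf1_2: float = np.nan
    qf2_2: float = np.nan
    qf3_2: float = np.nan
    q_ccc2: float = np.nan
    thresholds_passed: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)
             if f.name != "thresholds_passed"}
        return pd.Series(d)


def stratified_split(dataset: MoleculeDataset | Sequence[float], seed: int = 0,
                     n_strata: int = 3, n_folds: int = 4,
                     ids: Sequence[str] | None = None) -> SplitScheme:
    """Split compounds into activity terciles, then deal each stratum into folds.

    Fold sizes within a stratum differ by at most one; the four test sets are
    pairwise disjoint and jointly cover the dataset.
    """
    if isinstance(dataset, MoleculeDataset):
        y = dataset.y
        ids = dataset.ids
    else:
        y = np.asarray(dataset, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(y))]
    n = len(y)
    if n < n_strata * n_folds:
        raise ValueError(f"need at least {n_strata * n_folds} compounds, got {n}")

    # Stratum boundaries at activity terciles of the pooled dataset; rank-based
    # assignment keeps stratum sizes balanced under ties.
    order = np.argsort(y, kind="stable")
    strata = np.empty(n, dtype=int)
    for s, chunk in enumerate(np.array_split(order, n_strata)):
        strata[chunk] = s
    rng = np.random.default_rng(seed)
    assignments: dict[str, tuple[int, int]] = {}
    for s in range(n_strata):
        members = np.flatnonzero(strata == s)
        if len(members) < n_folds:
            raise ValueError(f"stratum {s} has only {len(members)} compounds; "
                             f"need at least {n_folds}")
        members = members[rng.permutation(len(members))]
        for j, idx in enumerate(members):
            assignments[ids[idx]] = (s, j % n_folds)
    assignments = {ids[i]: assignments[ids[i]] for i in range(n)}
    return SplitScheme(n_strata, n_folds, seed, assignments)


def golbraikh_tropsha(y_obs, y_pred) -> dict[str, float]:
    """Through-origin regression criteria for external predictivity.

    k = Σ(y·ŷ)/Σŷ²,  k′ = Σ(y·ŷ)/Σy²,
    r0² = 1 − Σ(y − k·ŷ)²/Σ(y − ȳ)²  (observed against the through-origin
    prediction line) and r′0² with the roles of y and ŷ swapped.
    """
    y = np.asarray(y_obs, float)
    yh = np.asarray(y_pred, float)
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(y) == 0 or np.ptp(yh) == 0:
        raise ValueError("constant vector: through-origin criteria undefined")
    syy = float(np.sum(yh * yh))
    soo = float(np.sum(y * y))
    if syy == 0 or soo == 0:
        raise ValueError("zero denominator in through-origin slope")
    k = float(np.sum(y * yh) / syy)
    k_prime = float(np.sum(y * yh) / soo)
    ss_o = float(np.sum((y - y.mean()) ** 2))
    ss_p = float(np.sum((yh - yh.mean()) ** 2))
    r0_2 = 1.0 - float(np.sum((y - k * yh) ** 2)) / ss_o
    r0p_2 = 1.0 - float(np.sum((yh - k_prime * y) ** 2)) / ss_p
    r2 = float(np.corrcoef(y, yh)[0, 1] ** 2)
    return {
        "k": k, "k_prime": k_prime, "r0_2": r0_2, "r0p_2": r0p_2, "r2": r2,
        "abs_r0_diff": abs(r0_2 - r0p_2),
        "rel_r0_gap": (r2 - r0_2) / r2,
        "rel_r0p_gap": (r2 - r0p_2) / r2,
    }


def rm2_metrics(r2: float, r0_2: float, r0p_2: float) -> dict[str, float]:
    """Roy's modified-r² family: rm² = r²(1 − √(r² − r0²)), its primed twin,
    their mean, and Δrm² = |rm² − r′m²|."""
    if min(r2, r0_2, r0p_2) < 0:
        raise ValueError("rm2 inputs must be non-negative")
    d1, d2 = r2 - r0_2, r2 - r0p_2
    if d1 < 0 or d2 < 0:
        logger.warning("r0² exceeds r² (%.3f/%.3f vs %.3f); clamping difference at 0",
                       r0_2, r0p_2, r2)
        d1, d2 = max(d1, 0.0), max(d2, 0.0)
    rm2 = r2 * (1.0 - np.sqrt(d1))
    rm2_prime = r2 * (1.0 - np.sqrt(d2))
    return {
        "rm2": float(rm2),
        "rm2_prime": float(rm2_prime),
        "rm2_bar": float((rm2 + rm2_prime) / 2.0),
        "delta_rm2": float(abs(rm2 - rm2_prime)),
    }


def external_q2(y_test_obs, y_test_pred, y_train_obs) -> dict[str, float]:
    """External q² variants referenced to the train mean (Q_F1), test mean
    (Q_F2) or train variance (Q_F3), plus Lin's concordance correlation.

    r_pred² is reported identically to Q_F1².
    """
    yt = np.asarray(y_test_obs, float)
    yp = np.asarray(y_test_pred, float)
    ytr = np.asarray(y_train_obs, float)
    if len(yt) == 0 or len(ytr) == 0:
        raise ValueError("empty test or train set")
    press = float(np.sum((yt - yp) ** 2))
    ss1 = float(np.sum((yt - ytr.mean()) ** 2))
    ss2 = float(np.sum((yt - yt.mean()) ** 2))
    ss3 = float(np.sum((ytr - ytr.mean()) ** 2))
    if ss1 == 0 or ss2 == 0 or ss3 == 0:
        raise ValueError("zero variance in reference set")
    qf1 = 1.0 - press / ss1
    qf2 = 1.0 - press / ss2
    qf3 = 1.0 - (press / len(yt)) / (ss3 / len(ytr))

    # Lin's concordance correlation coefficient of (observed, predicted).
    vy, vp = yt.var(), yp.var()
    cov = float(np.mean((yt - yt.mean()) * (yp - yp.mean())))
    ccc = 2.0 * cov / (vy + vp + (yt.mean() - yp.mean()) ** 2)
    return {"r_pred2": qf1, "qf1_2": qf1, "qf2_2": qf2, "qf3_2": qf3,
            "q_ccc2": float(ccc)}


def error_stats(y_obs, y_pred) -> dict[str, float]:
    """rss = Σe², rmse = √(rss/n), χ² = Σe²/|ŷ|, mae = |mean(e)|.

    ``mae`` follows the bias convention of the emulated toolchain's tables;
    ``mean_abs_error`` is the conventional mean of |e|.
    """
    y = np.asarray(y_obs, float)
    yh = np.asarray(y_pred, float)
    if len(y) != len(yh) or len(y) < 2:
        raise ValueError("need equal-length vectors of at least 2 points")
    e = y - yh
    rss = float(np.sum(e * e))
    nonzero = yh != 0
    if not np.all(nonzero):
        logger.warning("χ²: skipping %d term(s) with zero prediction", int((~nonzero).sum()))
    chi2 = float(np.sum(e[nonzero] ** 2 / np.abs(yh[nonzero])))
    return {
        "rss": rss,
        "rmse": float(np.sqrt(rss / len(y))),
        "chi2": chi2,
        "mae": float(abs(np.mean(e))),
        "mean_abs_error": float(np.mean(np.abs(e))),
    }


def metric_battery(y_train_obs, y_train_pred, y_test_obs, y_test_pred) -> MetricReport:
    """Full external battery for one train/test model (test-side statistics)."""
    gt = golbraikh_tropsha(y_test_obs, y_test_pred)
    rm = rm2_metrics(gt["r2"], max(gt["r0_2"], 0.0), max(gt["r0p_2"], 0.0))
    q = external_q2(y_test_obs, y_test_pred, y_train_obs)
    err = error_stats(y_test_obs, y_test_pred)
    rep = MetricReport()
    for d in (gt, rm, q):
        for key, val in d.items():
            if hasattr(rep, key):
                setattr(rep, key, val)
    for key in ("chi2", "rmse", "mae", "rss"):
        setattr(rep, key, err[key])
    return rep


#: Threshold battery; "all" = whole-dataset table, "set" = per-SET tables
#: (they differ only in the χ² bound).
def threshold_report(metrics: MetricReport, model: CvResult | None = None,
                     context: str = "set") -> dict[str, bool]:
    """Per-criterion pass flags at the published acceptance thresholds.

    Boundary values are inclusive where the thresholds are printed as
    inclusive (0.85 ≤ k ≤ 1.15).
    """
    chi2_bound = 0.5 if context == "all" else 1.0
    out: dict[str, bool] = {}
    if model is not None:
        out["q2>0.5"] = model.q2 > 0.5
        out["r2>0.6"] = model.r2 > 0.6
        out["F>100"] = model.f_value > 100.0
    m = metrics
    checks = {
        f"chi2<{chi2_bound}": m.chi2 < chi2_bound,
        "rmse<0.5": m.rmse < 0.5,
        "0.85<=k<=1.15": 0.85 <= m.k <= 1.15,
        "0.85<=k_prime<=1.15": 0.85 <= m.k_prime <= 1.15,
        "|r0_2-r0p_2|<0.3": m.abs_r0_diff < 0.3,
        "rel_r0_gap<0.1": m.rel_r0_gap < 0.1,
        "rel_r0p_gap<0.1": m.rel_r0p_gap < 0.1,
        "rm2>0.5": m.rm2 > 0.5,
        "rm2_prime>0.5": m.rm2_prime > 0.5,
        "rm2_bar>0.5": m.rm2_bar > 0.5,
        "delta_rm2<0.2": m.delta_rm2 < 0.2,
        "r_pred2>0.5": m.r_pred2 > 0.5,
    }
    for name, ok in checks.items():
        out[name] = False if _isnan_check(m, name) else bool(ok)
    metrics.thresholds_passed = out
    return out


def _isnan_check(m: MetricReport, name: str) -> bool:
    probe = {
        "chi2": m.chi2, "rmse": m.rmse, "0.85<=k": m.k, "0.85<=k_prime": m.k_prime,
        "|r0_2": m.abs_r0_diff, "rel_r0_gap": m.rel_r0_gap,
        "rel_r0p_gap": m.rel_r0p_gap, "rm2>": m.rm2, "rm2_prime": m.rm2_prime,
        "rm2_bar": m.rm2_bar, "delta_rm2": m.delta_rm2, "r_pred2": m.r_pred2,
    }
    for key, val in probe.items():
        if name.startswith(key):
            return bool(np.isnan(val))
    return False


def report_table(reports: dict[str, MetricReport],
                 cvs: dict[str, CvResult] | None = None) -> pd.DataFrame:
    """Battery as metric rows × SET columns, threshold column last."""
    thresholds = {
        "q2": ">0.5", "onc": "", "sep": "", "r2": ">0.6", "see": "<<1",
        "f_value": ">100", "bs_r2": "", "bs_sd": "", "chi2": "<1.0",
        "rmse": "<0.5", "mae": "~0", "rss": "", "k": "0.85<=k<=1.15",
        "k_prime": "0.85<=k'<=1.15", "r0_2": "~r2", "r0p_2": "~r2",
        "abs_r0_diff": "<0.3", "rel_r0_gap": "<0.1", "rel_r0p_gap": "<0.1",
        "rm2": ">0.5", "rm2_prime": ">0.5", "rm2_bar": ">0.5",
        "delta_rm2": "<0.2", "r_pred2": ">0.5", "qf1_2": "", "qf2_2": "",
        "qf3_2": "", "q_ccc2": "",
    }
    cols = {}
    for name, rep in reports.items():
        s = rep.as_series()
        if cvs is not None and name in cvs:
            cv = cvs[name]
            s = pd.concat([pd.Series({
                "q2": cv.q2, "onc": cv.onc, "sep": cv.sep, "r2_train": cv.r2,
                "see": cv.see, "f_value": cv.f_value,
                "bs_r2": cv.bs_r2, "bs_sd": cv.bs_sd}), s])
        cols[name] = s
    df = pd.DataFrame(cols)
    df["threshold"] = [thresholds.get(i.replace("_train", ""), "") for i in df.index]
    return df
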