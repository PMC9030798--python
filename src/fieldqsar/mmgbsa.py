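"""MM-PB/GBSA per-frame energy aggregation with interaction entropy.

End-state binding free energies decompose as

    ΔE_gas  = ΔE_vdW + ΔE_ele
    ΔG_sol  = ΔG_GB/PB + ΔG_SA
    ΔTOTAL  = ΔE_gas + ΔG_sol
    ΔG_bind = ΔTOTAL + TΔS_penalty

where TΔS_penalty ≥ 0 is the entropic penalty (−TΔS of the thermodynamic
decomposition, tabulated with a positive sign in MM-PB/GBSA reports) computed
by the interaction-entropy method: with E_int = E_vdW + E_ele per frame,

    TΔS_penalty = k_B·T · ln ⟨ exp((E_int − ⟨E_int⟩)/(k_B·T)) ⟩ ,

the exponential average of gas-phase interaction-energy fluctuations over the
last frames of the trajectory (evaluated via log-sum-exp; non-negative by
Jensen's inequality).  The PB/GB solves themselves are upstream: this module
consumes their per-frame term tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872041
DEFAULT_TEMPERATURE = 300.0

#: Snapshots used by default: the tail of the production trajectory.
DEFAULT_N_FRAMES = 500
DEFAULT_N_IE_FRAMES = 126

_COLUMN_ALIASES = {
    "vdw": ("vdw", "vdwaals", "van_der_waals"),
    "eel": ("eel", "ele", "elec", "eelec"),
    "egb_or_epb": ("egb", "epb", "egb_or_epb", "gb", "pb", "epol"),
    "esurf": ("esurf", "surf", "enpolar", "sa", "esa"),
}


@dataclass
class EnergySeries:
    """Per-frame MM-PB/GBSA energy terms, kcal/mol."""

    frame_index: np.ndarray
    vdw: np.ndarray
    eel: np.ndarray
    egb_or_epb: np.ndarray
    esurf: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    solvent_model: str = "GB"          # "GB" or "PB", by detected column
    dielectric_in: float | None = None  # ε_in metadata, passed through to reports

    def __post_init__(self) -> None:
        arrays = [self.frame_index, self.vdw, self.eel, self.egb_or_epb, self.esurf]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all term series must have equal length")
        if len(self.vdw) < 2:
            raise ValueError("need at least 2 frames")
        for name in ("vdw", "eel", "egb_or_epb", "esurf"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.vdw)

    def last(self, n: int) -> "EnergySeries":
        if n > len(self):
            raise ValueError(f"requested last {n} frames of a {len(self)}-frame series")
        return EnergySeries(self.frame_index[-n:], self.vdw[-n:], self.eel[-n:],
                            self.egb_or_epb[-n:], self.esurf[-n:],
                            self.temperature, self.solvent_model, self.dielectric_in)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame_index, "VDW": self.vdw, "EEL": self.eel,
            ("EGB" if self.solvent_model == "GB" else "EPB"): self.egb_or_epb,
            "ESURF": self.esurf,
        })


@dataclass
class BindingSummary:
    """Aggregated binding-energy terms: mean ± SD per component, kcal/mol."""

    means: dict[str, float]
    sds: dict[str, float]
    dg_gas: float
    dg_solv: float
    dtotal: float
    entropy_penalty: float | None = None
    dg_bind: float | None = None
    n_frames: int = 0

    def row(self) -> pd.Series:
        order = ["VDW", "EEL", "EGB_or_EPB", "ESURF",
                 "dG_gas", "dG_solv", "dTOTAL", "TdS", "dG_bind"]
        vals = {
            "VDW": self.means["vdw"], "EEL": self.means["eel"],
            "EGB_or_EPB": self.means["egb_or_epb"], "ESURF": self.means["esurf"],
            "dG_gas": self.dg_gas, "dG_solv": self.dg_solv, "dTOTAL": self.dtotal,
            "TdS": self.entropy_penalty, "dG_bind": self.dg_bind,
        }
        return pd.Series({k: vals[k] for k in order})


@dataclass
class ResidueSeries:
    """Per-frame binding-energy contribution of one residue."""

    label: str
    contributions: np.ndarray
    min_distance: float                  # closest approach to any ligand atom, Å

    @property
    def mean(self) -> float:
        return float(np.mean(self.contributions))


def read_energy_table(path: str | Path, dialect: str | None = None) -> EnergySeries:
    """Read a delimited per-frame energy table (GMX_MMPBSA-style output).

    Term columns are matched case-insensitively against common aliases
    (VDWAALS/VDW, EEL, EGB or EPB — auto-detecting the solvent model —
    ESURF); a missing term is an error naming the column.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect, None)
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    lower = {c.lower().strip(): c for c in df.columns}
    found: dict[str, str] = {}
    for term, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                found[term] = lower[a]
                break
        else:
            raise ValueError(f"missing energy term column for {term!r} "
                             f"(accepted names: {aliases}) in {path}")
    solvent = "PB" if found["egb_or_epb"].lower().startswith(("epb", "pb")) else "GB"
    if "frame" in lower:
        frames = df[lower["frame"]].to_numpy()
        order = np.argsort(frames, kind="stable")
        df = df.iloc[order]
        frames = frames[order]
    else:
        frames = np.arange(len(df))
    series = EnergySeries(
        frame_index=np.asarray(frames),
        vdw=df[found["vdw"]].to_numpy(float),
        eel=df[found["eel"]].to_numpy(float),
        egb_or_epb=df[found["egb_or_epb"]].to_numpy(float),
        esurf=df[found["esurf"]].to_numpy(float),
        solvent_model=solvent,
    )
    logger.info("read %d frame(s) from %s (%s solvent model)", len(series), path, solvent)
    return series


def write_energy_table(series: EnergySeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def aggregate(series: EnergySeries) -> BindingSummary:
    """Average per-frame terms and composites.

    Composites are summed per frame first, so ΔTOTAL = ΔE_gas + ΔG_sol holds
    identically and SDs are frame-wise SDs of the composite series.
    """
    gas = series.vdw + series.eel
    solv = series.egb_or_epb + series.esurf
    total = gas + solv
    terms = {"vdw": series.vdw, "eel": series.eel,
             "egb_or_epb": series.egb_or_epb, "esurf": series.esurf,
             "dg_gas": gas, "dg_solv": solv, "dtotal": total}
    means = {k: float(np.mean(v)) for k, v in terms.items()}
    sds = {k: float(np.std(v, ddof=1)) for k, v in terms.items()}
    return BindingSummary(means=means, sds=sds, dg_gas=means["dg_gas"],
                          dg_solv=means["dg_solv"], dtotal=means["dtotal"],
                          n_frames=len(series))


def interaction_entropy(series: EnergySeries,
                        n_last: int = DEFAULT_N_IE_FRAMES) -> float:
    """Interaction-entropy estimate of the entropic penalty, kcal/mol.

    Uses the gas-phase interaction energy E_int = E_vdW + E_ele over the last
    ``n_last`` frames; evaluated with log-sum-exp to guard against overflow.
    """
    if n_last > len(series):
        raise ValueError(f"n_last={n_last} exceeds frame count {len(series)}")
    sub = series.last(n_last)
    kt = KB * series.temperature
    e_int = sub.vdw + sub.eel
    z = (e_int - e_int.mean()) / kt
    penalty = kt * (logsumexp(z) - np.log(len(z)))
    return float(max(penalty, 0.0))


def final_binding(dtotal: float, entropy_penalty: float) -> float:
    """ΔG_bind = ΔTOTAL + TΔS_penalty (the penalty carries a positive sign)."""
    if not (np.isfinite(dtotal) and np.isfinite(entropy_penalty)):
        raise ValueError("non-finite inputs to final_binding")
    return dtotal + entropy_penalty


def summarize_binding(series: EnergySeries,
                      n_frames: int = DEFAULT_N_FRAMES,
                      n_ie_frames: int = DEFAULT_N_IE_FRAMES) -> BindingSummary:
    """Tail-of-trajectory aggregation + interaction entropy in one step."""
    sub = series.last(min(n_frames, len(series)))
    summary = aggregate(sub)
    summary.entropy_penalty = interaction_entropy(sub, min(n_ie_frames, len(sub)))
    summary.dg_bind = final_binding(summary.dtotal, summary.entropy_penalty)
    return summary


def per_residue_table(residues: Sequence[ResidueSeries],
                      distance_cutoff: float = 4.0,
                      negligible_cutoff: float = 0.5) -> pd.DataFrame:
    """Per-residue decomposition filtered by contact distance and magnitude.

    Residues farther than ``distance_cutoff`` from the ligand or contributing
    less than ``negligible_cutoff`` (by |mean|) are reported blank ("-").
    """
    if not residues:
        raise ValueError("empty residue list")
    labels = [r.label for r in residues]
    if len(set(labels)) != len(labels):
        raise ValueError("residue labels must be unique")
    rows = []
    for r in residues:
        keep = r.min_distance <= distance_cutoff and abs(r.mean) >= negligible_cutoff
        rows.append({
            "residue": r.label,
            "min_distance": r.min_distance,
            "mean_contribution": r.mean if keep else np.nan,
            "retained": keep,
            "display": f"{r.mean:.2f}" if keep else "-",
        })
    return pd.DataFrame(rows)


def summary_table(summaries: dict[str, BindingSummary]) -> pd.DataFrame:
    """Multi-complex table in the conventional 9-column order with ± SD."""
    sd_keys = {"VDW": "vdw", "EEL": "eel", "EGB_or_EPB": "egb_or_epb",
               "ESURF": "esurf", "dG_gas": "dg_gas", "dG_solv": "dg_solv",
               "dTOTAL": "dtotal"}
    rows = {}
    for name, s in summaries.items():
        row = {}
        for col, val in s.row().items():
            if col in sd_keys:
                row[col] = f"{val:.2f}±{s.sds[sd_keys[col]]:.2f}"
            elif val is None:
                row[col] = "-"
            else:
                row[col] = f"{val:.2f}"
        rows[name] = row
    return pd.DataFrame(rows).T
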