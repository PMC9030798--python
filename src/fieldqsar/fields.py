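"""CoMFA / CoMSIA molecular interaction fields on a rectilinear grid.

CoMFA probes every lattice point with an sp³ carbon of charge +1 and records

* a steric energy from a 12-6 Lennard-Jones potential,
  ``S(q) = Σ_i ε_iq [ (R_iq/r_iq)^12 − 2 (R_iq/r_iq)^6 ]``, and
* an electrostatic Coulomb energy with a distance-dependent dielectric
  ε(r) = r, ``E(q) = Σ_i 332.06 z_probe q_i / r_iq²``,

both truncated at an energy tolerance (default ±30 kcal/mol).  Inside a
sterically saturated envelope the Coulomb value is physically meaningless, so
it is replaced by that column's mean across compounds when the descriptor
matrix is assembled.

CoMSIA replaces the hard potentials with Gaussian similarity indices
``A_k(q) = − Σ_i w_probe,k w_ik exp(−α r_iq²)`` for property k ∈
{steric, electrostatic, hydrophobic, donor, acceptor}, with attenuation
factor α = 0.3 by default; atomic steric weights are proportional to
vdW volume (r³), electrostatic weights are partial charges, the rest come
from the atom-typing tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import (DEFAULT_LJ_EPSILON, LJ_EPSILON, AlignedMolecule,
                      MoleculeDataset)

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.06

COMFA_FIELDS = ("S", "E")
COMSIA_FIELDS = ("S", "E", "H", "D", "A")

#: Default column standard-deviation filter, in field units
#: (energy for CoMFA, similarity for CoMSIA).
DEFAULT_MIN_SIGMA = {"comfa": 2.0, "comsia": 0.5}


@dataclass(frozen=True)
class GridSpec:
    """A rectilinear lattice: origin corner, spacing and point counts."""

    origin: tuple[float, float, float]
    spacing: float = 2.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be at least 1")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All grid points, shape (n_points, 3), x fastest-varying last axis order."""
        axes = [np.asarray(self.origin)[i] + self.spacing * np.arange(self.dims[i])
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def translated(self, shift: Sequence[float]) -> "GridSpec":
        o = tuple(float(a + b) for a, b in zip(self.origin, shift))
        return GridSpec(o, self.spacing, self.dims)


@dataclass(frozen=True)
class ProbeSpec:
    """The lattice probe: an sp³ carbon cation by default."""

    charge: float = 1.0
    vdw_radius: float = 1.52
    lj_epsilon: float = 0.107
    property_weights: dict = field(default_factory=lambda: {k: 1.0 for k in COMSIA_FIELDS})

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.lj_epsilon <= 0:
            raise ValueError("probe radius and epsilon must be positive")


@dataclass(frozen=True)
class FieldConfig:
    energy_cutoff: float = 30.0
    attenuation_alpha: float = 0.3
    min_sigma: float | None = None  # resolved per method when None
    field_set: tuple[str, ...] = COMSIA_FIELDS
    #: When True, all atoms (not only the probe) use the 1.52 Å probe radius.
    uniform_atom_radius: bool = False

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy cutoff must be positive")
        if not 0 < self.attenuation_alpha < 1:
            raise ValueError("attenuation alpha must be in (0, 1)")
        unknown = set(self.field_set) - set(COMSIA_FIELDS)
        if unknown:
            raise ValueError(f"unknown field labels: {sorted(unknown)}")


@dataclass
class DescriptorMatrix:
    """Filtered, block-scaled field descriptors: compounds × grid columns.

    ``column_meta`` carries (grid point index, field label) per retained
    column; ``block_scaling`` the per-field scale factors; ``column_means``
    the pre-scaling training means used for the electrostatic masking of
    new compounds.
    """

    values: np.ndarray
    column_meta: list[tuple[int, str]]
    block_scaling: dict[str, float]
    dropped_columns: np.ndarray
    ids: list[str]
    grid: GridSpec
    method: str
    probe: ProbeSpec
    config: FieldConfig
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length must equal column count")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        """Row subset by compound id, keeping filter and scaling fixed."""
        index = {i: k for k, i in enumerate(self.ids)}
        sel = [index[i] for i in ids]
        return DescriptorMatrix(self.values[sel], self.column_meta,
                                self.block_scaling, self.dropped_columns,
                                list(ids), self.grid, self.method,
                                self.probe, self.config, self.column_means)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{label}@{pt}" for pt, label in self.column_meta]
        return pd.DataFrame(self.values, index=self.ids, columns=cols)


def build_grid(dataset: MoleculeDataset | Sequence[AlignedMolecule],
               spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Build a lattice covering every molecule plus a margin on all sides."""
    molecules = dataset.molecules if isinstance(dataset, MoleculeDataset) else list(dataset)
    if not molecules:
        raise ValueError("cannot build a grid for an empty dataset")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((h - l) / spacing - 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(tuple(float(v) for v in lo), spacing, dims)


def _pairwise_r(mol: AlignedMolecule, grid: GridSpec) -> np.ndarray:
    """Distances grid-point × atom, Å, floored to avoid singularities."""
    d = grid.points()[:, None, :] - mol.coords[None, :, :]
    return np.maximum(np.sqrt(np.sum(d * d, axis=2)), 1e-8)


def comfa_fields(mol: AlignedMolecule, grid: GridSpec, probe: ProbeSpec,
                 cfg: FieldConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steric and electrostatic probe energies at every grid point.

    Returns (steric, electrostatic, saturated) where ``saturated`` marks
    points whose unclamped steric energy reached the +cutoff tolerance —
    i.e. points inside the molecular envelope.
    """
    r = _pairwise_r(mol, grid)
    if cfg.uniform_atom_radius:
        radii = np.full(len(mol.atoms), probe.vdw_radius)
    else:
        radii = mol.vdw_radii
    R = radii + probe.vdw_radius
    eps = np.sqrt(np.array([LJ_EPSILON.get(a.element, DEFAULT_LJ_EPSILON)
                            for a in mol.atoms]) * probe.lj_epsilon)
    ratio6 = (R[None, :] / r) ** 6
    steric_raw = np.sum(eps[None, :] * (ratio6 * ratio6 - 2.0 * ratio6), axis=1)
    saturated = steric_raw >= cfg.energy_cutoff
    steric = np.clip(steric_raw, -cfg.energy_cutoff, cfg.energy_cutoff)

    # distance-dependent dielectric ε(r) = r  ⇒  1/(ε r) = 1/r²
    elec_raw = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges[None, :] / (r * r), axis=1)
    elec = np.clip(elec_raw, -cfg.energy_cutoff, cfg.energy_cutoff)
    return steric, elec, saturated


def comsia_fields(mol: AlignedMolecule, grid: GridSpec, probe: ProbeSpec,
                  cfg: FieldConfig) -> dict[str, np.ndarray]:
    """Gaussian similarity indices at every grid point, one array per field."""
    weights: dict[str, np.ndarray] = {}
    for label in cfg.field_set:
        if label == "S":
            w = np.array([a.vdw_radius ** 3 for a in mol.atoms])
        elif label == "E":
            w = mol.charges
        elif label == "H":
            w = np.array([a.hydrophobicity for a in mol.atoms])
        elif label == "D":
            w = np.array([1.0 if a.is_donor else 0.0 for a in mol.atoms])
        elif label == "A":
            w = np.array([1.0 if a.is_acceptor else 0.0 for a in mol.atoms])
        else:
            raise ValueError(f"unknown field label {label!r}")
        weights[label] = w
    r2 = _pairwise_r(mol, grid) ** 2
    g = np.exp(-cfg.attenuation_alpha * r2)
    out = {}
    for label, w in weights.items():
        wp = probe.property_weights.get(label, 1.0)
        out[label] = -wp * (g @ w)
    return out


def assemble_descriptor_matrix(dataset: MoleculeDataset,
                               grid: GridSpec | None = None,
                               probe: ProbeSpec | None = None,
                               cfg: FieldConfig | None = None,
                               method: str = "comfa") -> DescriptorMatrix:
    """Stack per-compound fields, mask, filter and block-scale them.

    Column filtering drops columns whose standard deviation over compounds
    is below ``min_sigma``; block scaling rescales each field block so every
    block contributes equal total variance (CoMFA-standard scaling).
    """
    if method not in ("comfa", "comsia"):
        raise ValueError(f"method must be 'comfa' or 'comsia', got {method!r}")
    probe = probe or ProbeSpec()
    if cfg is None:
        cfg = FieldConfig(field_set=COMFA_FIELDS if method == "comfa" else COMSIA_FIELDS)
    grid = grid or build_grid(dataset)
    n = len(dataset)
    p = grid.n_points
    labels = COMFA_FIELDS if method == "comfa" else tuple(cfg.field_set)

    blocks = {label: np.empty((n, p)) for label in labels}
    if method == "comfa":
        sat = np.empty((n, p), dtype=bool)
        for i, mol in enumerate(dataset.molecules):
            s, e, m = comfa_fields(mol, grid, probe, cfg)
            blocks["S"][i], blocks["E"][i], sat[i] = s, e, m
        # Coulomb values inside a steric envelope are meaningless: replace by
        # the column mean over compounds outside the envelope at that point.
        n_out = np.maximum((~sat).sum(axis=0), 1)
        col_mean = np.where(~sat, blocks["E"], 0.0).sum(axis=0) / n_out
        blocks["E"] = np.where(sat, col_mean[None, :], blocks["E"])
    else:
        for i, mol in enumerate(dataset.molecules):
            vals = comsia_fields(mol, grid, probe, cfg)
            for label in labels:
                blocks[label][i] = vals[label]

    raw = np.concatenate([blocks[label] for label in labels], axis=1)
    meta = [(pt, label) for label in labels for pt in range(p)]

    min_sigma = cfg.min_sigma if cfg.min_sigma is not None else DEFAULT_MIN_SIGMA[method]
    sd = raw.std(axis=0, ddof=1) if n > 1 else np.zeros(raw.shape[1])
    keep = sd >= min_sigma
    if not np.any(keep):
        raise ValueError(
            f"all {raw.shape[1]} columns filtered at min_sigma={min_sigma}; "
            "molecules may be identical or the threshold too high")
    dropped = np.flatnonzero(~keep)
    kept_meta = [meta[j] for j in np.flatnonzero(keep)]
    values = raw[:, keep]
    col_means = values.mean(axis=0)

    # Block scaling: each field block ends with total variance 1.
    scaling: dict[str, float] = {}
    kept_labels = np.array([m[1] for m in kept_meta])
    var = values.var(axis=0, ddof=1)
    for label in labels:
        mask = kept_labels == label
        total = var[mask].sum()
        scale = 1.0 / np.sqrt(total) if total > 0 else 1.0
        scaling[label] = float(scale)
        values[:, mask] *= scale

    logger.info("%s descriptor matrix: %d compounds × %d columns "
                "(%d dropped at min_sigma=%.3g)", method, n, values.shape[1],
                len(dropped), min_sigma)
    return DescriptorMatrix(values, kept_meta, scaling, dropped, dataset.ids,
                            grid, method, probe, cfg, column_means=col_means)


def project_molecules(dm: DescriptorMatrix,
                      molecules: Sequence[AlignedMolecule]) -> DescriptorMatrix:
    """Compute descriptors for new compounds in an existing matrix's space.

    Uses the same grid, filter, masking means and block scaling as the
    training matrix, so rows are directly comparable/predictable.
    """
    labels = COMFA_FIELDS if dm.method == "comfa" else tuple(dm.config.field_set)
    p = dm.grid.n_points
    n = len(molecules)
    blocks = {label: np.empty((n, p)) for label in labels}
    sat = np.zeros((n, p), dtype=bool)
    for i, mol in enumerate(molecules):
        if dm.method == "comfa":
            s, e, m = comfa_fields(mol, dm.grid, dm.probe, dm.config)
            blocks["S"][i], blocks["E"][i], sat[i] = s, e, m
        else:
            vals = comsia_fields(mol, dm.grid, dm.probe, dm.config)
            for label in labels:
                blocks[label][i] = vals[label]
    raw = np.concatenate([blocks[label] for label in labels], axis=1)
    meta = [(pt, label) for label in labels for pt in range(p)]
    keep = np.ones(len(meta), dtype=bool)
    keep[dm.dropped_columns] = False
    values = raw[:, keep]
    if dm.method == "comfa":
        sat_full = np.concatenate([np.zeros_like(sat), sat], axis=1)[:, keep]
        values = np.where(sat_full, dm.column_means[None, :], values)
    kept_labels = np.array([m[1] for m in dm.column_meta])
    for label in labels:
        values[:, kept_labels == label] *= dm.block_scaling[label]
    return DescriptorMatrix(values, dm.column_meta, dm.block_scaling,
                            dm.dropped_columns, [m.id for m in molecules],
                            dm.grid, dm.method, dm.probe, dm.config,
                            dm.column_means)


def write_descriptor_matrix(dm: DescriptorMatrix, path, sidecar=None) -> None:
    """Serialize matrix values as CSV plus a column-metadata sidecar."""
    dm.to_frame().to_csv(path)
    if sidecar is not None:
        pts = dm.grid.points()
        rows = [{"column": f"{label}@{pt}", "field": label, "point": pt,
                 "x": pts[pt, 0], "y": pts[pt, 1], "z": pts[pt, 2],
                 "block_scale": dm.block_scaling[label]}
                for pt, label in dm.column_meta]
        pd.DataFrame(rows).to_csv(sidecar, index=False)
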