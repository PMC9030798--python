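"""Molecule and activity I/O for field-based 3D-QSAR.

This module holds the in-memory containers shared across the package
(:class:`Atom`, :class:`AlignedMolecule`, :class:`MoleculeDataset`), readers
for pre-aligned small-molecule files (SDF V2000 and Tripos MOL2, parsed with
RDKit), IC50 → pIC50 conversion, dataset assembly, and a least-squares rigid
superposition onto a shared scaffold.

Atom typing
-----------
Closed modelling suites assign proprietary atom types; here the physicochemical
property flags and weights used by the similarity fields are derived from open,
reproducible rules collected in the tables below:

* van der Waals radii: Bondi element radii (Å);
* Lennard-Jones well depths: Tripos-style element values (kcal/mol);
* hydrogen-bond donors: N or O bearing at least one hydrogen;
* hydrogen-bond acceptors: N or O that is not positively charged;
* hydrophobicity weights: carbon and halogens positive, polar heteroatoms
  negative; atoms carrying a large partial charge (|q| > 0.35 e) are treated
  as polar regardless of element.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

# Bondi van der Waals radii, Å.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

# Tripos-style Lennard-Jones well depths, kcal/mol.
LJ_EPSILON = {
    "H": 0.042, "C": 0.107, "N": 0.095, "O": 0.116, "F": 0.109, "P": 0.314,
    "S": 0.314, "Cl": 0.314, "Br": 0.434, "I": 0.623,
}
DEFAULT_LJ_EPSILON = 0.107

# Dimensionless hydrophobicity weights: lipophilic atoms positive,
# polar atoms negative.
HYDROPHOBICITY = {
    "C": 1.0, "F": 0.5, "Cl": 0.8, "Br": 0.9, "I": 1.0, "S": 0.4,
    "H": 0.0, "N": -1.0, "O": -1.0, "P": -0.5,
}
DEFAULT_HYDROPHOBICITY = 0.0

#: Partial-charge magnitude above which an atom is treated as polar
#: when assigning hydrophobicity weights, elementary charge units.
POLAR_CHARGE_CUTOFF = 0.35

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


@dataclass
class Atom:
    """One atom of an aligned molecule.

    position is in Å in the dataset's shared coordinate frame;
    partial_charge in elementary charge units.
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = DEFAULT_VDW_RADIUS
    hydrophobicity: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


@dataclass
class AlignedMolecule:
    """A 3D molecule in the dataset's common coordinate frame."""

    id: str
    atoms: list[Atom]
    core_atom_indices: list[int] | None = None
    #: Underlying RDKit molecule when the structure came from (or is destined
    #: for) a connection-table file format; not used by field computation.
    rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"molecule {self.id!r} has zero atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "AlignedMolecule":
        atoms = [replace(a, position=np.asarray(xyz, dtype=float))
                 for a, xyz in zip(self.atoms, coords)]
        return AlignedMolecule(self.id, atoms, self.core_atom_indices, self.rdkit_mol)


@dataclass
class ActivityRecord:
    compound_id: str
    pIC50: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pIC50):
            raise ValueError(f"non-finite pIC50 for {self.compound_id!r}")


@dataclass
class MoleculeDataset:
    """Aligned molecules matched one-to-one with activities.

    Molecules lacking an activity record are kept in ``excluded_ids`` so the
    exclusion is visible rather than silent.
    """

    molecules: list[AlignedMolecule]
    activities: list[ActivityRecord]
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mol_ids = [m.id for m in self.molecules]
        act_ids = [a.compound_id for a in self.activities]
        if mol_ids != act_ids:
            raise ValueError("molecules and activities must match one-to-one, in order")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def y(self) -> np.ndarray:
        return np.array([a.pIC50 for a in self.activities], dtype=float)

    def subset(self, ids: Sequence[str]) -> "MoleculeDataset":
        index = {m.id: i for i, m in enumerate(self.molecules)}
        rows = [index[i] for i in ids]
        return MoleculeDataset([self.molecules[i] for i in rows],
                               [self.activities[i] for i in rows])


def _assign_properties(mol: Chem.Mol, charges: np.ndarray) -> list[Atom]:
    """Build Atom records from an RDKit molecule using the open rule tables."""
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    for i, a in enumerate(mol.GetAtoms()):
        el = a.GetSymbol()
        q = float(charges[i])
        donor = acceptor = False
        if el in ("N", "O"):
            has_h = any(n.GetAtomicNum() == 1 for n in a.GetNeighbors())
            has_h = has_h or a.GetTotalNumHs() > 0
            donor = has_h
            acceptor = a.GetFormalCharge() <= 0
        hyd = HYDROPHOBICITY.get(el, DEFAULT_HYDROPHOBICITY)
        if abs(q) > POLAR_CHARGE_CUTOFF:
            hyd = min(hyd, -1.0)
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(
            element=el,
            position=np.array([pos.x, pos.y, pos.z]),
            partial_charge=q,
            vdw_radius=VDW_RADII.get(el, DEFAULT_VDW_RADIUS),
            hydrophobicity=hyd,
            is_donor=donor,
            is_acceptor=acceptor,
        ))
    return atoms


def gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    """Iterative partial-equalization (Gasteiger–Marsili) charges via RDKit.

    Atoms for which the iteration does not converge get charge 0.
    """
    m = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(m)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()])
    return np.where(np.isfinite(q), q, 0.0)


def _stored_sdf_charges(mol: Chem.Mol) -> np.ndarray | None:
    if mol.HasProp("PARTIAL_CHARGES"):
        vals = np.array([float(v) for v in mol.GetProp("PARTIAL_CHARGES").split()])
        if len(vals) == mol.GetNumAtoms():
            return vals
    return None


def from_rdkit(mol: Chem.Mol, mol_id: str, charges: np.ndarray | None = None) -> AlignedMolecule:
    """Convert an RDKit molecule (with a 3D conformer) into an AlignedMolecule."""
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"molecule {mol_id!r} has zero atoms")
    if charges is None:
        charges = gasteiger_charges(mol)
    core = None
    if mol.HasProp("CORE_ATOM_INDICES"):
        core = [int(v) for v in mol.GetProp("CORE_ATOM_INDICES").split()]
    return AlignedMolecule(mol_id, _assign_properties(mol, np.asarray(charges, float)),
                           core_atom_indices=core, rdkit_mol=mol)


def read_molecules(path: str | Path, format: str | None = None) -> list[AlignedMolecule]:
    """Read aligned molecules from an SDF (V2000) or MOL2 file.

    Stored partial charges (MOL2 charge column, or an SDF ``PARTIAL_CHARGES``
    tag) are used verbatim; molecules without charges get Gasteiger-style
    assignment.  Property flags are derived from the module rule tables.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("sdf", "mol2"):
        raise ValueError(f"unsupported format {format!r}: expected 'sdf' or 'mol2'")
    if not path.exists():
        raise FileNotFoundError(path)

    molecules: list[AlignedMolecule] = []
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparseable SDF record at index {i} in {path}")
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                logger.warning("record %d in %s failed sanitization; kept as-is", i, path)
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            mol_id = name or f"MOL{i:03d}"
            charges = _stored_sdf_charges(mol)
            molecules.append(from_rdkit(mol, mol_id, charges))
    else:
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
        if not blocks:
            raise ValueError(f"no MOLECULE record found in {path}")
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
            if mol is None:
                raise ValueError(f"unparseable MOL2 record at index {i} in {path}")
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                logger.warning("record %d in %s failed sanitization; kept as-is", i, path)
            charges = None
            if all(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms()):
                charges = np.array([a.GetDoubleProp("_TriposPartialCharge")
                                    for a in mol.GetAtoms()])
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            molecules.append(from_rdkit(mol, name or f"MOL{i:03d}", charges))

    logger.info("read %d molecule(s) from %s", len(molecules), path)
    return molecules


def write_sdf(molecules: Iterable[AlignedMolecule], path: str | Path) -> None:
    """Write molecules as an SDF with partial charges in a ``PARTIAL_CHARGES`` tag.

    Requires each molecule to carry its RDKit connection table; the written
    conformer coordinates are taken from the AlignedMolecule (i.e. the aligned
    frame), so a write-then-read round trip preserves the shared frame.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for m in molecules:
            if m.rdkit_mol is None:
                raise ValueError(f"molecule {m.id!r} has no connection table to write")
            mol = Chem.Mol(m.rdkit_mol)
            conf = mol.GetConformer()
            for i, a in enumerate(m.atoms):
                conf.SetAtomPosition(i, a.position.tolist())
            mol.SetProp("_Name", m.id)
            mol.SetProp("PARTIAL_CHARGES",
                        " ".join(f"{a.partial_charge:.6f}" for a in m.atoms))
            if m.core_atom_indices is not None:
                mol.SetProp("CORE_ATOM_INDICES",
                            " ".join(str(i) for i in m.core_atom_indices))
            writer.write(mol)
    finally:
        writer.close()


def ic50_to_pic50(ic50: float, unit: str = "nM") -> float:
    """Convert an IC50 concentration to pIC50 = −log10(IC50 in mol/L)."""
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50 * _UNIT_FACTORS[unit])


def pic50_to_ic50(pic50: float, unit: str = "nM") -> float:
    """Inverse of :func:`ic50_to_pic50`."""
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return 10.0 ** (-pic50) / _UNIT_FACTORS[unit]


def read_activity_table(path: str | Path, default_unit: str = "nM") -> list[ActivityRecord]:
    """Read a delimited activity table with header ``compound_id,activity,unit``.

    ``unit`` may be a concentration unit (M, mM, uM/µM, nM — converted to
    pIC50) or the literal ``pIC50`` (taken as-is).  Unlabeled rows default to
    nM, the conventional unit of medicinal-chemistry IC50 tables; the applied
    unit is echoed in the log.
    """
    df = pd.read_csv(path)
    required = {"compound_id", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        unit = str(row["unit"]) if "unit" in df.columns and pd.notna(row.get("unit")) else default_unit
        if unit == "pIC50":
            p = float(row["activity"])
        else:
            p = ic50_to_pic50(float(row["activity"]), unit)
        records.append(ActivityRecord(str(row["compound_id"]), p))
    logger.info("read %d activity record(s) from %s (default unit %s)",
                len(records), path, default_unit)
    return records


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    df = pd.DataFrame([{"compound_id": r.compound_id, "activity": r.pIC50,
                        "unit": "pIC50"} for r in records])
    df.to_csv(path, index=False)


def assemble_dataset(molecules: Sequence[AlignedMolecule],
                     activity_table: Sequence[ActivityRecord]) -> MoleculeDataset:
    """Match molecules with activities into a dataset.

    Molecules without an activity are recorded in ``excluded_ids``; an
    activity referring to an unknown molecule is an error.  Output order is
    sorted by compound id, so assembly is invariant to input order.
    """
    mol_ids = [m.id for m in molecules]
    if len(set(mol_ids)) != len(mol_ids):
        dupes = sorted({i for i in mol_ids if mol_ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")
    act_ids = [a.compound_id for a in activity_table]
    if len(set(act_ids)) != len(act_ids):
        dupes = sorted({i for i in act_ids if act_ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids in activity table: {dupes}")
    mol_index = {m.id: m for m in molecules}
    for a in activity_table:
        if a.compound_id not in mol_index:
            raise ValueError(f"activity for unknown compound id {a.compound_id!r}")
    act_index = {a.compound_id: a for a in activity_table}

    kept = sorted(i for i in mol_ids if i in act_index)
    excluded = sorted(i for i in mol_ids if i not in act_index)
    if len(kept) < 10:
        raise ValueError(f"need at least 10 molecules with activities, got {len(kept)}")
    y = np.array([act_index[i].pIC50 for i in kept])
    if np.ptp(y) <= 0:
        raise ValueError("dataset activity spread must be positive")
    logger.info("assembled dataset: %d kept, %d excluded (%s)",
                len(kept), len(excluded), ", ".join(excluded) or "none")
    return MoleculeDataset([mol_index[i] for i in kept],
                           [act_index[i] for i in kept], excluded)


def align_to_core(mol: AlignedMolecule, template: AlignedMolecule,
                  core_map: Sequence[tuple[int, int]]) -> tuple[AlignedMolecule, float]:
    """Rigidly superpose ``mol`` onto ``template`` over mapped core atoms.

    ``core_map`` lists (mol_atom_index, template_atom_index) pairs.  Returns
    the transformed molecule and the post-fit RMSD over the mapped atoms.
    This is a least-squares (Kabsch) superposition — a convenience
    approximation of database alignment for pre-built 3D structures.
    """
    if len(core_map) < 3:
        raise ValueError(f"need at least 3 mapped atom pairs, got {len(core_map)}")
    mi = [p[0] for p in core_map]
    ti = [p[1] for p in core_map]
    P = mol.coords[mi]
    Q = template.coords[ti]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("mapped core atoms are collinear; superposition is ill-posed")
    rot, _ = Rotation.align_vectors(Qc, Pc)
    new_coords = rot.apply(mol.coords - P.mean(axis=0)) + Q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[mi] - Q) ** 2, axis=1))))
    logger.debug("aligned %s onto %s: core RMSD %.4f Å", mol.id, template.id, rmsd)
    return mol.with_coords(new_coords), rmsd
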