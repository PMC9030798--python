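"""Synthetic congeneric series and MD-like energy series with known truth.

The molecule generator emulates the structure of a medicinal-chemistry
lead-optimization dataset: every compound shares a rigid isoindolinone
bicyclic core and varies at three substituent positions (the lactam nitrogen
and two aromatic carbons) drawn from a library of small fragments.  3D
structures are embedded from SMILES with a seeded distance-geometry method,
relaxed with MMFF, charged with Gasteiger's scheme, and rigidly superposed
on the shared core so the whole series lives in one coordinate frame.

Activities are *planted in field space*: a coefficient vector β is drawn in
the row space of the centered canonical steric+electrostatic descriptor
matrix, the linear response Xβ is perturbed with Gaussian noise of the
requested SD, and the result is mapped affinely onto the pIC50 range
[5.3, 9.2] typical of a potent congeneric series.  Because the response is
generated from true field descriptors, recovering β exercises the whole
fields → PLS path, and the noiseless case is exactly linear.

The energy generator emulates the tail of an MM-PB/GBSA trajectory: each
term is a stationary AR(1) Gaussian with requested mean, SD and lag-1
autocorrelation (MD energy terms are autocorrelated, and the interaction
entropy depends on that fluctuation structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import (ActivityRecord, AlignedMolecule, MoleculeDataset,
                      align_to_core, from_rdkit, gasteiger_charges)
from .fields import DescriptorMatrix, assemble_descriptor_matrix
from .mmgbsa import EnergySeries

logger = logging.getLogger(__name__)

CORE_SMILES = "O=C1NCc2ccccc21"
_TEMPLATE = "O=C1N({r1})Cc2cc({r2})cc({r3})c21"

#: Substituent fragment library (SMILES branches): varying element, charge
#: distribution and bulk, including H-bond donors/acceptors and halogens.
SUBSTITUENTS = (
    "[H]", "C", "CC", "C(C)C", "O", "OC", "N", "CO", "CN",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "SC", "S(=O)(=O)C",
)

DEFAULT_ACTIVITY_RANGE = (5.3, 9.2)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated series: the planted linear model."""

    planted_coefficients: np.ndarray   # per retained descriptor column
    noise_sd: float                    # pIC50 units (pre-rescaling scale)
    seed: int
    core_template: AlignedMolecule
    descriptors: DescriptorMatrix | None = field(default=None, repr=False)
    activity_range: tuple[float, float] = DEFAULT_ACTIVITY_RANGE

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class EnergyGenSpec:
    """Per-term mean/SD, frame count and AR(1) autocorrelation for MD-like series."""

    means: tuple[float, float, float, float] = (-54.40, -35.03, 39.06, -6.63)
    sds: tuple[float, float, float, float] = (2.82, 3.67, 2.67, 0.12)
    n_frames: int = 500
    autocorrelation: float = 0.5
    seed: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 <= self.autocorrelation < 1:
            raise ValueError("autocorrelation must be in [0, 1)")


def _build_compound(choices: tuple[str, str, str], mol_id: str,
                    embed_seed: int) -> AlignedMolecule:
    smiles = _TEMPLATE.format(r1=choices[0], r2=choices[1], r3=choices[2])
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"failed to build compound from {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = embed_seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    charges = gasteiger_charges(mol)
    am = from_rdkit(mol, mol_id, charges)
    core_query = Chem.MolFromSmiles(CORE_SMILES)
    match = mol.GetSubstructMatch(core_query)
    if not match:
        raise RuntimeError(f"core not found in {smiles!r}")
    am.core_atom_indices = list(match)
    return am


def make_congeneric_series(
    n_compounds: int = 40,
    noise_sd: float = 0.3,
    seed: int = 0,
    substituent_library: Sequence[str] = SUBSTITUENTS,
    activity_range: tuple[float, float] = DEFAULT_ACTIVITY_RANGE,
    method: str = "comfa",
) -> tuple[MoleculeDataset, SyntheticTruth]:
    """Generate an aligned congeneric series with planted field-space activities.

    Same seed ⇒ identical molecules, coordinates, charges and activities.
    """
    if n_compounds < 20:
        raise ValueError(f"need at least 20 compounds, got {n_compounds}")
    lib = list(substituent_library)
    rng = np.random.default_rng(seed)

    picks = [tuple(lib[j] for j in rng.integers(0, len(lib), size=3))
             for _ in range(n_compounds)]
    if len(set(picks)) == 1:
        raise ValueError("degenerate generator spec: every compound is identical")

    molecules: list[AlignedMolecule] = []
    template: AlignedMolecule | None = None
    for i, choice in enumerate(picks):
        mol_id = f"C{i + 1:03d}"
        embed_seed = int(rng.integers(1, 2**31 - 1))
        am = _build_compound(choice, mol_id, embed_seed)
        if template is None:
            template = am
        else:
            core_map = list(zip(am.core_atom_indices, template.core_atom_indices))
            am, rmsd = align_to_core(am, template, core_map)
            if rmsd > 0.5:
                logger.warning("core RMSD %.2f Å for %s after superposition", rmsd, mol_id)
        molecules.append(am)

    # Provisional dataset (flat activities) just to define grid and descriptors.
    placeholder = [ActivityRecord(m.id, float(i)) for i, m in enumerate(molecules)]
    provisional = MoleculeDataset(list(molecules), placeholder)
    dm = assemble_descriptor_matrix(provisional, method=method)

    # Plant β in the row space of centered X so the noiseless response is
    # exactly realizable and the minimum-norm solution recovers β itself.
    Xc = dm.values - dm.values.mean(axis=0)
    alpha = rng.standard_normal(dm.n_compounds)
    beta = Xc.T @ alpha
    signal = Xc @ beta
    sd = signal.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate generator spec: planted signal has no variance")
    beta /= sd
    signal /= sd
    noisy = signal + rng.normal(0.0, noise_sd, size=n_compounds)

    lo, hi = activity_range
    span = noisy.max() - noisy.min()
    y = lo + (hi - lo) * (noisy - noisy.min()) / span

    # Dataset rows follow assemble-order (sorted ids); C001.. sorts naturally.
    activities = [ActivityRecord(m.id, float(yy)) for m, yy in zip(molecules, y)]
    dataset = MoleculeDataset(molecules, activities)
    truth = SyntheticTruth(
        planted_coefficients=beta * (hi - lo) / span,
        noise_sd=noise_sd, seed=seed, core_template=template,
        descriptors=dm, activity_range=activity_range,
    )
    logger.info("generated %d-compound congeneric series (seed %d, noise_sd %.3g)",
                n_compounds, seed, noise_sd)
    return dataset, truth


def make_energy_series(spec: EnergyGenSpec) -> EnergySeries:
    """Stationary AR(1) Gaussian energy terms with requested means and SDs."""
    rng = np.random.default_rng(spec.seed)
    phi = spec.autocorrelation
    n = spec.n_frames
    terms = []
    for mu, sd in zip(spec.means, spec.sds):
        if sd == 0:
            terms.append(np.full(n, mu))
            continue
        x = np.empty(n)
        x[0] = rng.normal(0.0, sd)
        innov_sd = sd * np.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t - 1]
        terms.append(mu + x)
    vdw, eel, egb, esurf = terms
    return EnergySeries(np.arange(n), vdw, eel, egb, esurf,
                        temperature=spec.temperature)
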