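# Methods

## Scope and model

`fieldqsar` implements the classic field-based 3D-QSAR workflow for a
pre-aligned congeneric series, plus end-state MM-PB/GBSA binding-energy
aggregation.  The package takes ligand geometries as given: conformer
generation, docking, MD and the PB/GB solvers themselves are upstream of its
inputs.  Its central assumptions are those of the CoMFA family — that the
compounds share one bioactive alignment, that activity differences are
explained by differences in the steric/electrostatic (and, for CoMSIA,
hydrophobic and H-bonding) environment sampled on a lattice around the
series, and that a low-dimensional PLS latent structure links the two.

## Descriptor fields

A rectilinear grid covers the union of all molecules with a margin
(default 4.0 Å) at a spacing of 2.0 Å.  The probe is an sp³ carbon with
charge +1.0 e, van der Waals radius 1.52 Å and Lennard-Jones well depth
0.107 kcal/mol.

**CoMFA.**  Steric: `S(q) = Σᵢ ε_iq[(R_iq/r_iq)¹² − 2(R_iq/r_iq)⁶]` with
`R_iq = rᵢ + r_probe` and `ε_iq = √(εᵢ ε_probe)`; atom radii are Bondi
values and well depths Tripos-style element values (a config switch forces
the 1.52 Å probe radius onto all atoms for users who read that convention
differently).  Electrostatic: `E(q) = 332.06 q_i/(ε(r) r_iq)` with the
distance-dependent dielectric ε(r) = r, i.e. a 1/r² law (the default of the
toolchain this emulates).  Both are clamped to ±30 kcal/mol (the energy
tolerance).  At points where the unclamped steric energy reaches the
+tolerance — i.e. inside a molecule's envelope — the Coulomb value is
meaningless and is replaced by the column mean over the compounds that do
not bury that point; new compounds projected into a fitted matrix reuse the
training columns' means.

**CoMSIA.**  `A_k(q) = −Σᵢ w_probe,k w_ik exp(−α r_iq²)` with α = 0.3.
Atomic property weights: steric ∝ r_vdw³ (volume), electrostatic = partial
charge, hydrophobic from a small open element table (C and halogens
positive, N/O/P negative, atoms with |q| > 0.35 e treated as polar), donor
and acceptor = 0/1 flags (donor: N/O bearing H; acceptor: N/O not positively
charged).  These open rules replace the proprietary atom typing of
commercial suites and are collected in one source file (`chem_io`).

**Matrix assembly.**  Columns with standard deviation below `min_sigma`
(2.0 kcal/mol for CoMFA, 0.5 similarity units for CoMSIA, both configurable)
are dropped; each surviving field block is rescaled so that every block
contributes equal total variance (CoMFA-standard block scaling).  The filter
and scaling are fixed from the training block and reused for test compounds
and inside cross-validation — the convention of the emulated toolchain, and a
known (documented) source of mild optimism in q².

## PLS and internal statistics

`fit_pls` is a NIPALS-style fit (scikit-learn `PLSRegression`, unscaled X —
scaling is the descriptor matrix's job).  LOO validation computes, per
component count c, `q²(c) = 1 − PRESS(c)/Σ(y−ȳ)²` with every compound
predicted by a model that excluded it.  Because NIPALS is sequential
(WᵀP triangular), truncating the weight/loading sequence of a c_max fit
reproduces the c-component model exactly; one fit per left-out compound
therefore yields all component counts, and a test verifies this path against
the naive n×c refit loop at 1e-8.  The optimal number of components is the
argmax of q² over 1..max_components (ties → fewer components; the selection
rule is logged since conventions differ), with SEP = √(PRESS/(n−c−1)),
SEE = √(RSS/(n−c−1)) and F = (r²/c)/((1−r²)/(n−c−1)).  Bootstrap r²
defaults to 100 resamples.  Contours are StDev\*Coeff (coefficient × column
SD) mapped back to grid coordinates, exportable as a point list or an
OpenDX grid; per-field percent contributions are Σ|β|·SD per block,
normalized to 100.

## Splitting and the validation battery

Compounds are ranked into three activity terciles (high/medium/low), each
stratum is shuffled with a seeded generator and dealt into four folds; fold
k of every stratum is the test set of SET k.  The four test sets are
pairwise disjoint, cover the dataset exactly once and give a ~3:1
train:test ratio.

The battery implements: k = Σyŷ/Σŷ², k′ = Σyŷ/Σy²,
r0² = 1 − Σ(y−kŷ)²/Σ(y−ȳ)² (and r′0² with roles swapped);
rm² = r²(1−√(r²−r0²)), its primed twin, their mean and
Δrm² = |rm²−r′m²| (the literature definition); Q_F1² (train-mean
reference, reported identically as r_pred²), Q_F2² (test mean), Q_F3²
(train variance per observation); Lin's concordance correlation; and
χ² = Σe²/|ŷ| (the χ² convention is not standardized — this common QSAR
reading is logged).  MAE is reported as |mean(e)|, a bias measure, because
that is the only reading consistent with reference tables that print
MAE ≈ 0 beside RMSE ≈ 0.3; the conventional mean-absolute-error is exposed
as `mean_abs_error`.  Threshold flags follow the published acceptance
columns (q² > 0.5, r² > 0.6, F > 100, χ² < 0.5 whole-dataset / < 1.0
per-SET, RMSE < 0.5, 0.85 ≤ k, k′ ≤ 1.15 inclusive, |r0²−r′0²| < 0.3,
relative gaps < 0.1, rm² family > 0.5, Δrm² < 0.2, r_pred² > 0.5).

## Applicability domain and scrambling

Leverage is computed in latent-score space, `h_i = 1/n + t_iᵀ(TᵀT)⁻¹t_i`:
with thousands of grid columns for ~10² compounds the descriptor-space hat
matrix is degenerate, and the score space carries exactly the dimensions the
model uses.  Training leverages sum to c+1.  The warning leverage is
h\* = 3(p+1)/n with p the number of descriptor *field blocks* (2 for S+E
CoMFA, 4 for an SEAD CoMSIA) — the convention that reproduces the published
bounds of this workflow family; the textbook parameter-count convention is
available via `convention="parameters"`.  Standardized residuals are fitted
residuals over the RMSE of the respective set (Williams-plot convention);
compounds with h > h\* or |σ| > 3 are flagged.

Progressive scrambling sorts compounds by activity, cuts them into b
contiguous bins and permutes activities within bins: b = n leaves the
response untouched (r²_yy′ = 1), b = 1 scrambles it fully (r²_yy′ ≈ 0), so
the bin count grades the perturbation.  Default bins 2–10 with 20 seeded
permutations each.  Quadratics of the scrambled LOO q² and SDEP against
r²_yy′ are evaluated at the critical perturbation r²_yy′ = 0.85, giving Q²,
cSDEP and the slope dq²/dr²_yy′ (robust models score a slope below ~1.2).
The exact perturbation operator of the commercial implementation is
undocumented; this one is deterministic and stated in full.

## MM-PB/GBSA aggregation

Per-frame tables (GMX_MMPBSA-style delimited text; VDW/VDWAALS, EEL,
EGB or EPB auto-detected, ESURF) are aggregated over the trajectory tail
(default: last 500 snapshots).  Composites are summed per frame first, so
ΔTOTAL = ΔE_gas + ΔG_sol holds identically and the reported SDs are
frame-wise SDs of the composite series (not error-propagated).  The entropy
term uses the interaction-entropy estimator over the last 126 snapshots by
default, evaluated via log-sum-exp; it is non-negative by Jensen's
inequality and enters with a positive sign:
ΔG_bind = ΔTOTAL + TΔS_penalty.  The sign convention follows the table
arithmetic of MM-PB/GBSA reports, where the tabulated "TΔS" is the positive
penalty −TΔS of the thermodynamic decomposition.  Temperature defaults to
300 K (k_B·T = 0.596 kcal/mol); the interior dielectric ε_in = 5 is carried
as metadata only — the solvers that used it run upstream.  Per-residue
decompositions keep residues within 4.0 Å of the ligand contributing at
least 0.5 kcal/mol in magnitude; all others are reported blank.

## Synthetic data generator

`make_congeneric_series` emulates a lead-optimization dataset: every
compound is an isoindolinone (benzene-fused five-membered lactam) decorated
at three attachment points (the lactam nitrogen and two aromatic carbons)
with fragments from a 16-member library spanning alkyl, halogen, nitrile,
trifluoromethyl, thioether, sulfone and H-bonding groups.  Structures are
embedded from SMILES with seeded distance geometry (ETKDG), relaxed with
MMFF, charged with Gasteiger's partial-equalization scheme, and rigidly
superposed on the shared core, so the series lives in one frame with small
residual core RMSD (< 0.5 Å; the ring conformers are nearly rigid).

Activities are planted in field space: a coefficient vector β is drawn in
the **row space** of the centered canonical CoMFA matrix (β = X_cᵀα with
Gaussian α), which makes the noiseless recovery problem well-posed despite
p ≫ n — the minimum-norm PLS solution converges to β itself, so planted-
coefficient recovery is a genuine integration test of the fields → PLS
path.  The linear response is normalized to unit SD, Gaussian noise of the
requested SD (default 0.3 pIC50 units) is added, and the result is mapped
affinely onto [5.3, 9.2] — the potency span of a typical nanomolar
congeneric series.  The affine step rescales the effective noise by the
ratio of the target span to the realized span (≈ 0.8–1.0 at n ≥ 40), which
is accepted as part of the stated generation model.  With the defaults
(noise 0.3, n = 160) the pipeline lands at LOO q² ≈ 0.85–0.9 — inside the
well-validated regime of field-QSAR models — and a permuted response drives
q² below zero.

What the generator does *not* emulate: conformational flexibility and
alignment ambiguity, activity cliffs, assay heterogeneity, correlated
(non-Gaussian) activity noise, and real binding-site constraints.  Tests
passing on this generator therefore demonstrate the correctness of the
statistical machinery and field computation, not the predictivity of any
model on real compounds.

`make_energy_series` draws each energy term as a stationary AR(1) Gaussian
with requested mean, SD and lag-1 autocorrelation (default 0.5): MD energy
terms are autocorrelated, and the interaction-entropy estimator is
sensitive to exactly that fluctuation structure.

## Numerical choices and degenerate inputs

Grid/atom distances are floored at 1e-8 Å so a grid point coinciding with
an atom takes the energy clamp, never an infinity.  Column SDs use ddof=1.
The LOO q² denominator uses the full-set mean.  ONC ties break toward fewer
components.  Zero-RMSE Williams inputs (a numerically perfect model) are an
error, as are constant responses in LOO, all-constant descriptor matrices,
collinear superposition cores, and empty reference sets in the external
metrics.  r0² > r² inputs to rm² clamp the difference at zero with a
warning.  Bin counts exceeding n are skipped with a warning.  All stochastic
stages (splitting, bootstrap, scrambling, generation) take explicit seeds;
the CLI forks one root seed into named per-stage substreams so stages
reproduce independently of execution order.

## Problem sizes in tests

The test suite exercises the pipeline at the sizes a desk study of this
workflow needs: 20–40-compound series for exactness/recovery checks, ten
160-compound series for the noisy-regime Monte-Carlo check, 20
permutations per scrambling limit, and 500-frame energy series.  These
sizes were chosen as the package's own verification design; the statistical
assertions (q² band, null q² ≤ 0, 3-SE mean recovery) are formulated at
tolerances appropriate to those sizes.

## Known limitations

* Alignment is a convenience least-squares core superposition; database
  alignment of flexible molecules is out of scope, and pre-aligned input is
  the primary path.
* Atom typing is deliberately simple and open; it will not reproduce
  proprietary typing atom-for-atom.
* The ONC selection rule and in-fold filtering conventions of commercial
  PLS implementations vary; this package's choices are stated above and
  logged at run time.
* The MAE and χ² conventions follow the emulated report format, not every
  textbook definition (both alternatives are exposed or documented).
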