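# fieldqsar

Field-based 3D-QSAR and end-state binding-energy analysis for congeneric
small-molecule series, aimed at computational medicinal chemists who want a
scriptable, fully reproducible version of the classic CoMFA/CoMSIA workflow:

* **CoMFA / CoMSIA descriptor fields** — an sp³ C⁺¹ probe samples a 2.0 Å
  lattice around the aligned series; CoMFA records Lennard-Jones steric and
  Coulomb electrostatic energies (ε(r) = r, ±30 kcal/mol tolerance), CoMSIA
  records Gaussian similarity indices
  `A_k(q) = −Σᵢ w_probe,k · w_ik · exp(−α r_iq²)` (α = 0.3) for steric,
  electrostatic, hydrophobic, H-bond donor and acceptor properties.
* **PLS regression** with leave-one-out validation (q², optimal number of
  components, SEP), the no-validation fit (r², SEE, F), bootstrap r², and
  StDev\*Coeff contour export with per-field percent contributions.
* **Validation battery** — stratified 4-fold train/test splitting (activity
  terciles, ~3:1 ratio), Golbraikh–Tropsha through-origin criteria
  (k, k′, r0², r′0²), Roy's rm² family, Q_F1²/Q_F2²/Q_F3², Lin's concordance
  correlation, χ²/RMSE/MAE, and a pass/fail report at the conventional
  thresholds (q² > 0.5, r² > 0.6, 0.85 ≤ k ≤ 1.15, rm² > 0.5, …).
* **Diagnostics** — applicability-domain (Williams plot) analysis with
  score-space leverages and warning leverage h\* = 3(p+1)/n, and progressive
  response scrambling with Q², cSDEP and the sensitivity slope dq²/dr²_yy′
  at the critical perturbation r²_yy′ = 0.85.
* **MM-PB/GBSA aggregation** — per-frame energy-term tables are aggregated as
  ΔE_gas = ΔE_vdW + ΔE_ele, ΔG_sol = ΔG_GB/PB + ΔG_SA,
  ΔTOTAL = ΔE_gas + ΔG_sol, with the entropic penalty from the
  interaction-entropy method,
  TΔS = k_B·T·ln⟨exp((E_int − ⟨E_int⟩)/k_B·T)⟩ ≥ 0, and
  ΔG_bind = ΔTOTAL + TΔS; plus distance/magnitude-filtered per-residue
  decomposition tables.
* **Synthetic data** — a seeded generator of aligned isoindolinone congeneric
  series whose activities are planted in true field-descriptor space, and of
  AR(1) MD-like energy series, so the entire pipeline is testable with known
  ground truth.

## Worked example

```bash
fieldqsar synth --n 40 --noise-sd 0.3 --seed 5 --energy --out-dir demo
fieldqsar qsar --config demo/config.yaml --max-components 8
fieldqsar ad --config demo/config.yaml
fieldqsar scramble --config demo/config.yaml
fieldqsar mmgbsa --config demo/config.yaml demo/energy.csv --out-dir demo
```

The same run through the Python API:

```python
>>> from fieldqsar import synthdata, pls_qsar
>>> dataset, truth = synthdata.make_congeneric_series(160, noise_sd=0.3, seed=0)
>>> cv = pls_qsar.loo_validate(truth.descriptors, dataset.y, max_components=10)
>>> print(f"q2={cv.q2:.3f} onc={cv.onc} r2={cv.r2:.3f}")
q2=0.882 onc=5 r2=0.939
```

q² is the leave-one-out cross-validated determination coefficient (how well
each compound is predicted by a model that never saw it), the ONC the
component count maximizing it, and r² the fit quality of the final model at
that component count — here comfortably above the conventional q² > 0.5 /
r² > 0.6 acceptance bar, as expected for a series with a planted linear
field–activity relationship and 0.3 pIC50 units of noise.

The `mmgbsa` step prints one 9-column row per complex, e.g.

```
        VDW          EEL          EGB_or_EPB  ESURF       dG_gas       dG_solv     dTOTAL       TdS   dG_bind
energy  -55.02±2.59  -35.13±3.63  38.96±2.91  -6.63±0.12  -90.15±4.40  32.33±2.90  -57.82±5.13  8.75  -49.07
```

— mean ± SD of each term over the trajectory tail, the gas/solvation sums,
the interaction-entropy penalty, and the final binding free energy (kcal/mol).

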