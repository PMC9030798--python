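import numpy as np
import pytest

from fieldqsar.chem_io import (ActivityRecord, AlignedMolecule, Atom,
                               MoleculeDataset)
from fieldqsar.fields import (COULOMB_CONSTANT, FieldConfig, GridSpec,
                              ProbeSpec, assemble_descriptor_matrix,
                              build_grid, comfa_fields, comsia_fields,
                              project_molecules)


def _mol(mol_id, atoms):
    return AlignedMolecule(mol_id, atoms)


def _carbon(pos, charge=0.0, **kw):
    return Atom("C", np.asarray(pos, float), partial_charge=charge,
                vdw_radius=1.70, hydrophobicity=1.0, **kw)


def _dataset(mols):
    acts = [ActivityRecord(m.id, 5.0 + i) for i, m in enumerate(mols)]
    return MoleculeDataset(mols, acts)


class TestBuildGrid:
    def test_single_atom_margin4_spacing2_gives_5cubed(self):
        ds = _dataset([_mol("A", [_carbon([0, 0, 0])])])
        grid = build_grid(ds, spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)
        center = grid.points().mean(axis=0)
        np.testing.assert_allclose(center, [0, 0, 0], atol=1e-12)

    def test_translated_copy_enlarges_grid(self):
        base = _mol("A", [_carbon([0, 0, 0])])
        far = _mol("B", [_carbon([10, 0, 0])])
        g1 = build_grid(_dataset([base]), 2.0, 4.0)
        g2 = build_grid(MoleculeDataset([base, far],
                                        [ActivityRecord("A", 5.0),
                                         ActivityRecord("B", 6.0)]), 2.0, 4.0)
        assert g2.dims[0] > g1.dims[0]
        assert g2.dims[1:] == g1.dims[1:]

    def test_default_spacing_is_2A(self):
        ds = _dataset([_mol("A", [_carbon([0, 0, 0])])])
        assert build_grid(ds).spacing == 2.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestComfaFields:
    probe = ProbeSpec()
    cfg = FieldConfig(field_set=("S", "E"))

    def test_distant_point_fields_vanish(self):
        mol = _mol("A", [_carbon([0, 0, 0], charge=0.02)])
        grid = GridSpec((100.0, 0.0, 0.0), 2.0, (1, 1, 1))
        s, e, sat = comfa_fields(mol, grid, self.probe, self.cfg)
        assert abs(s[0]) < 1e-3 and abs(e[0]) < 1e-3
        assert not sat[0]

    def test_clamp_bounds_all_values(self):
        mol = _mol("A", [_carbon([0, 0, 0], charge=1.0)])
        grid = GridSpec((-2.0, -2.0, -2.0), 1.0, (5, 5, 5))  # points inside atom
        s, e, sat = comfa_fields(mol, grid, self.probe, self.cfg)
        assert np.all(np.abs(s) <= 30.0) and np.all(np.abs(e) <= 30.0)
        assert sat.any()

    def test_lj_minimum_closed_form(self):
        # probe at r = R_iq exactly: steric = −ε_iq = −√(ε_C ε_probe)
        R = 1.70 + 1.52
        mol = _mol("A", [_carbon([0, 0, 0])])
        grid = GridSpec((R, 0.0, 0.0), 2.0, (1, 1, 1))
        s, e, _ = comfa_fields(mol, grid, self.probe, self.cfg)
        assert s[0] == pytest.approx(-np.sqrt(0.107 * 0.107), abs=1e-12)
        assert e[0] == 0.0

    def test_coulomb_distance_dependent_dielectric(self):
        mol = _mol("A", [_carbon([0, 0, 0], charge=0.25)])
        r = 5.0
        grid = GridSpec((r, 0.0, 0.0), 2.0, (1, 1, 1))
        _, e, _ = comfa_fields(mol, grid, self.probe, self.cfg)
        assert e[0] == pytest.approx(COULOMB_CONSTANT * 0.25 / r**2, rel=1e-12)

    def test_additive_over_atoms(self):
        a = _mol("A", [_carbon([0, 0, 0], charge=0.2)])
        b = _mol("B", [_carbon([3, 0, 0], charge=-0.1)])
        ab = _mol("AB", a.atoms + b.atoms)
        grid = GridSpec((6.0, 1.0, 0.0), 2.0, (2, 2, 2))
        sa, ea, _ = comfa_fields(a, grid, self.probe, self.cfg)
        sb, eb, _ = comfa_fields(b, grid, self.probe, self.cfg)
        sab, eab, _ = comfa_fields(ab, grid, self.probe, self.cfg)
        np.testing.assert_allclose(sab, sa + sb, atol=1e-10)
        np.testing.assert_allclose(eab, ea + eb, atol=1e-10)


class TestComsiaFields:
    probe = ProbeSpec()
    cfg = FieldConfig()

    def test_coincident_atom_contributes_minus_weight(self):
        atom = Atom("C", np.zeros(3), partial_charge=0.3, vdw_radius=1.0,
                    hydrophobicity=1.0, is_donor=True, is_acceptor=True)
        mol = _mol("A", [atom])
        grid = GridSpec((0.0, 0.0, 0.0), 2.0, (1, 1, 1))
        vals = comsia_fields(mol, grid, self.probe, self.cfg)
        assert vals["S"][0] == pytest.approx(-1.0)       # r_vdw³ = 1
        assert vals["E"][0] == pytest.approx(-0.3)
        assert vals["H"][0] == pytest.approx(-1.0)
        assert vals["D"][0] == pytest.approx(-1.0)
        assert vals["A"][0] == pytest.approx(-1.0)

    def test_doubling_alpha_shrinks_magnitude(self):
        mol = _mol("A", [_carbon([0, 0, 0], charge=0.4)])
        grid = GridSpec((2.0, 1.0, 0.0), 2.0, (2, 1, 1))
        lo = comsia_fields(mol, grid, self.probe, FieldConfig(attenuation_alpha=0.3))
        hi = comsia_fields(mol, grid, self.probe, FieldConfig(attenuation_alpha=0.6))
        for k in lo:
            assert np.all(np.abs(hi[k]) < np.abs(lo[k]) + 1e-15)

    def test_two_atom_gaussian_oracle(self):
        a1 = Atom("C", np.array([0.0, 0.0, 0.0]), partial_charge=0.2,
                  vdw_radius=1.7, hydrophobicity=1.0)
        a2 = Atom("O", np.array([1.5, 0.0, 0.0]), partial_charge=-0.4,
                  vdw_radius=1.52, hydrophobicity=-1.0, is_acceptor=True)
        mol = _mol("A", [a1, a2])
        q = np.array([2.0, 1.0, -1.0])
        grid = GridSpec(tuple(q), 2.0, (1, 1, 1))
        vals = comsia_fields(mol, grid, self.probe, self.cfg)
        alpha = 0.3
        g = [np.exp(-alpha * np.sum((q - a.position) ** 2)) for a in (a1, a2)]
        assert vals["S"][0] == pytest.approx(-(g[0] * 1.7**3 + g[1] * 1.52**3), abs=1e-10)
        assert vals["E"][0] == pytest.approx(-(g[0] * 0.2 + g[1] * -0.4), abs=1e-10)
        assert vals["H"][0] == pytest.approx(-(g[0] * 1.0 + g[1] * -1.0), abs=1e-10)
        assert vals["A"][0] == pytest.approx(-g[1], abs=1e-10)
        assert vals["D"][0] == pytest.approx(0.0, abs=1e-10)

    def test_unknown_field_label_rejected(self):
        with pytest.raises(ValueError):
            FieldConfig(field_set=("S", "X"))


class TestDescriptorMatrix:
    def test_identical_molecules_all_columns_filtered(self):
        mol = _mol("A", [_carbon([0, 0, 0], charge=0.2)])
        mols = [AlignedMolecule(f"M{i}", mol.atoms) for i in range(5)]
        with pytest.raises(ValueError, match="filtered"):
            assemble_descriptor_matrix(_dataset(mols))

    def test_block_scaling_equalizes_field_variance(self, series20):
        _, truth = series20
        dm = truth.descriptors
        labels = np.array([m[1] for m in dm.column_meta])
        var = dm.values.var(axis=0, ddof=1)
        vs = var[labels == "S"].sum()
        ve = var[labels == "E"].sum()
        assert vs == pytest.approx(ve, abs=1e-8)

    def test_matrix_reproduces_per_point_fields(self, series20):
        dataset, truth = series20
        dm = truth.descriptors
        i = 3
        s, e, _ = comfa_fields(dataset.molecules[i], dm.grid, dm.probe, dm.config)
        raw = np.concatenate([s, e])
        keep = np.ones(2 * dm.grid.n_points, bool)
        keep[dm.dropped_columns] = False
        labels = np.array([m[1] for m in dm.column_meta])
        unscaled = dm.values[i].copy()
        for lab in ("S", "E"):
            unscaled[labels == lab] /= dm.block_scaling[lab]
        steric_cols = labels == "S"
        np.testing.assert_allclose(unscaled[steric_cols],
                                   raw[keep][steric_cols], atol=1e-10)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        mols = [_mol(f"M{i}", [_carbon(rng.normal(scale=2, size=3),
                                       charge=rng.normal(scale=0.2))
                               for _ in range(4)]) for i in range(6)]
        ds = _dataset(mols)
        grid = build_grid(ds, 2.0, 3.0)
        cfg = FieldConfig(min_sigma=0.0, field_set=("S", "E"))
        dm = assemble_descriptor_matrix(ds, grid=grid, cfg=cfg)
        shift = np.array([1.3, -0.7, 2.1])
        mols2 = [m.with_coords(m.coords + shift) for m in mols]
        ds2 = MoleculeDataset(mols2, ds.activities)
        dm2 = assemble_descriptor_matrix(ds2, grid=grid.translated(shift), cfg=cfg)
        np.testing.assert_allclose(dm.values, dm2.values, atol=1e-10)

    def test_projection_matches_training_rows(self, series20):
        dataset, truth = series20
        dm = truth.descriptors
        proj = project_molecules(dm, dataset.molecules[:5])
        np.testing.assert_allclose(proj.values, dm.values[:5], atol=1e-10)

    def test_electrostatic_masking_uses_column_mean(self):
        # one compound saturates the probe at the grid point, one does not
        near = _mol("A", [_carbon([0.0, 0.0, 0.0], charge=0.5)])
        far = _mol("B", [_carbon([4.0, 0.0, 0.0], charge=-0.5)])
        ds = _dataset([near, far])
        grid = GridSpec((0.0, 0.0, 0.0), 2.0, (1, 1, 1))
        cfg = FieldConfig(min_sigma=0.0, field_set=("S", "E"))
        dm = assemble_descriptor_matrix(ds, grid=grid, cfg=cfg)
        labels = np.array([m[1] for m in dm.column_meta])
        e_col = dm.values[:, labels == "E"].ravel() / dm.block_scaling["E"]
        _, e_far, _ = comfa_fields(far, grid, dm.probe, cfg)
        # the saturated compound's Coulomb value is replaced by the
        # unsaturated column mean (here: the other compound's value)
        assert e_col[0] == pytest.approx(e_far[0], abs=1e-10)
        assert e_col[1] == pytest.approx(e_far[0], abs=1e-10)
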