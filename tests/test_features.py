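import numpy as np
import pytest
from rdkit import Chem

from gutshield import descriptors as D
from gutshield import fingerprints as FP
from gutshield.dataio import MoleculeDataset, MoleculeRecord
from gutshield.features import (
    FeatureSpec,
    FeatureSpecError,
    apply_scaler,
    build_feature_set,
    enumerate_specs,
    fit_scaler,
)


class TestFingerprints:
    @pytest.mark.parametrize("kind,width", list(FP.FINGERPRINT_WIDTHS.items()))
    def test_widths(self, kind, width):
        fp = FP.compute_fingerprint(Chem.MolFromSmiles("CCO"), kind)
        assert fp.shape == (width,)
        assert set(np.unique(fp)) <= {0, 1}

    def test_methane_maccs_near_all_zero(self):
        fp = FP.compute_fingerprint(Chem.MolFromSmiles("C"), "MACCS")
        assert fp.sum() <= 3

    @pytest.mark.parametrize("pair", [("ECFP4-1", "ECFP4-2"), ("ECFP6-1", "ECFP6-2")])
    def test_ecfp_or_folding_property(self, pair, sample_molecules):
        narrow, wide = pair
        for mol in sample_molecules:
            fp_wide = FP.compute_fingerprint(mol, wide)
            fp_narrow = FP.compute_fingerprint(mol, narrow)
            refolded = fp_wide[:1024] | fp_wide[1024:]
            assert np.array_equal(refolded, fp_narrow)

    @pytest.mark.parametrize("kind", FP.FINGERPRINT_KINDS)
    def test_invariant_to_atom_ordering(self, kind):
        a = Chem.MolFromSmiles("c1ccccc1CCN")
        b = Chem.MolFromSmiles("NCCc1ccccc1")
        assert np.array_equal(FP.compute_fingerprint(a, kind), FP.compute_fingerprint(b, kind))

    def test_unknown_kind_rejected(self):
        with pytest.raises(FP.FingerprintError):
            FP.compute_fingerprint(Chem.MolFromSmiles("C"), "FCFP")


class TestDescriptors:
    def test_ethanol_counts(self):
        vals = D.compute_13md(Chem.MolFromSmiles("CCO"))
        assert vals["n-HBD"] == 1
        assert vals["n-HBA"] == 1
        assert vals["n-AR"] == 0

    def test_benzene_rings(self):
        vals = D.compute_13md(Chem.MolFromSmiles("c1ccccc1"))
        assert vals["n-AR"] == 1
        assert vals["n-R"] == 1

    def test_water_molecular_weight(self):
        vals = D.compute_13md(Chem.MolFromSmiles("O"))
        assert vals["MW"] == pytest.approx(18.02, abs=0.01)

    def test_panel_has_13_members(self):
        assert len(D.PANEL_13MD) == 13
        vals = D.compute_13md(Chem.MolFromSmiles("CCO"))
        assert list(vals) == list(D.PANEL_13MD)

    def test_rdmd_full_panel(self):
        vals = D.compute_rdmd(Chem.MolFromSmiles("CCO"))
        assert len(vals) == len(D.rdmd_names())
        assert len(vals) > 100


class TestScaler:
    def _fm(self, values):
        from gutshield.features import FeatureMatrix

        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            values=values,
            feature_names=[f"13MD:{D.PANEL_13MD[i]}" for i in range(values.shape[1])],
            spec=FeatureSpec(descriptors="13MD"),
            ids=[f"m{i}" for i in range(values.shape[0])],
            descriptor_mask=np.ones(values.shape[1], dtype=bool),
        )

    def test_minmax_formula(self):
        fm = self._fm([[2.0], [4.0], [6.0]])
        scaled = apply_scaler(fit_scaler(fm), fm)
        assert scaled.values[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_external_values_clip(self):
        train = self._fm([[2.0], [6.0]])
        state = fit_scaler(train)
        out = apply_scaler(state, self._fm([[8.0], [0.0]]))
        assert out.values[:, 0] == pytest.approx([1.0, 0.0])

    def test_constant_column_maps_to_zero(self):
        fm = self._fm([[5.0], [5.0], [5.0]])
        scaled = apply_scaler(fit_scaler(fm), fm)
        assert np.all(scaled.values == 0.0)

    def test_scaling_invariance_random_matrices(self, rng):
        for _ in range(20):
            fm = self._fm(rng.normal(size=(12, 3)) * rng.uniform(1, 50))
            scaled = apply_scaler(fit_scaler(fm), fm).values
            assert scaled.min(axis=0) == pytest.approx([0, 0, 0], abs=0)
            assert scaled.max(axis=0) == pytest.approx([1, 1, 1], abs=0)

    def test_nan_imputed_with_train_median(self):
        train = self._fm([[1.0], [3.0], [5.0]])
        state = fit_scaler(train)
        out = apply_scaler(state, self._fm([[np.nan]]))
        assert out.values[0, 0] == pytest.approx(0.5)  # median 3 -> scaled 0.5

    def test_spec_mismatch_rejected(self):
        fm = self._fm([[1.0], [2.0]])
        state = fit_scaler(fm)
        state.spec_name = "MACCS"
        with pytest.raises(FeatureSpecError):
            apply_scaler(state, fm)


class TestFeatureSpec:
    def test_name_and_parse_round_trip(self):
        spec = FeatureSpec(fingerprint="MACCS", descriptors="13MD")
        assert spec.name == "13MD+MACCS"
        assert FeatureSpec.parse("13MD+MACCS") == spec

    def test_empty_spec_rejected(self):
        with pytest.raises(FeatureSpecError):
            FeatureSpec()

    def test_default_grid_is_18_sets(self):
        specs = enumerate_specs()
        assert len(specs) == 18
        assert len({s.name for s in specs}) == 18

    def test_descriptor_only_specs_appended(self):
        specs = enumerate_specs(include_descriptor_only=True)
        assert len(specs) == 20
        assert "13MD" in {s.name for s in specs}


class TestBuildFeatureSet:
    def _dataset(self, smiles):
        return MoleculeDataset(
            records=[MoleculeRecord(id=f"m{i}", smiles=s, label=0) for i, s in enumerate(smiles)]
        )

    def test_concatenated_width_13md_maccs(self):
        ds = self._dataset(["CCO", "c1ccccc1", "CCN"])
        fm = build_feature_set(ds, FeatureSpec.parse("13MD+MACCS"))
        assert fm.values.shape == (3, 166 + 13)
        assert fm.descriptor_mask.sum() == 13
        assert not fm.descriptor_mask[:166].any()

    def test_fingerprint_only_width(self):
        ds = self._dataset(["CCO", "c1ccccc1"])
        fm = build_feature_set(ds, FeatureSpec(fingerprint="MACCS"))
        assert fm.values.shape == (2, 166)

    def test_column_names_unique_and_stable(self):
        ds = self._dataset(["CCO", "c1ccccc1"])
        a = build_feature_set(ds, FeatureSpec.parse("13MD+MACCS"))
        b = build_feature_set(ds, FeatureSpec.parse("13MD+MACCS"))
        assert a.feature_names == b.feature_names
        assert len(set(a.feature_names)) == len(a.feature_names)

    def test_scaled_descriptor_columns_in_unit_interval(self, planted_dataset):
        ds, _ = planted_dataset
        fm = build_feature_set(ds, FeatureSpec.parse("13MD+MACCS"))
        desc = fm.values[:, fm.descriptor_mask]
        assert desc.min() >= 0.0 and desc.max() <= 1.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            build_feature_set(MoleculeDataset(records=[]), FeatureSpec(fingerprint="MACCS"))
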