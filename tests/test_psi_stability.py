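import numpy as np
import pandas as pd
import pytest

from degronkit.psi_stability import (DEFAULT_CATEGORY_QUANTILES, PSIRegressor,
                                     StabilityCategory, TerminalPeptide,
                                     TerminusKind, categorize_psi,
                                     featurize_terminus, linear_gravy_effect,
                                     load_gps_table, load_model, predict_psi,
                                     save_model, synthesize_psi_dataset,
                                     terminal_peptide, train_psi)
from degronkit.seqio import ProteinRecord


class TestFeaturizer:
    def test_poly_alanine_composition_and_gravy(self):
        f = featurize_terminus("A" * 23, TerminusKind.C)
        for prefix in ("full", "w10", "w8", "w6", "w4", "w2"):
            assert f[f"{prefix}_comp_A"] == pytest.approx(1.0)
            assert f[f"{prefix}_gravy"] == pytest.approx(1.8)

    def test_window_set_and_effective_lengths(self):
        f = featurize_terminus("ACDEFGHIKLMNPQRSTVWYACD", TerminusKind.C)
        assert f["full_len"] == 23.0
        for w in (10, 8, 6, 4, 2):
            assert f[f"w{w}_len"] == float(w)
        short = featurize_terminus("ACD", TerminusKind.C)
        assert short["w10_len"] == 3.0      # truncates to available residues

    def test_windows_from_correct_terminus(self):
        pep = "ACDEFGHIKLMNPQRSTVWYACD"
        n = featurize_terminus(pep, TerminusKind.N_MET_CLEAVED)
        c = featurize_terminus(pep, TerminusKind.C)
        assert n["w2_comp_A"] == pytest.approx(0.5)   # "AC"
        assert c["w2_comp_C"] == pytest.approx(0.5)   # "CD"

    def test_met_retained_windows_exclude_initiator(self):
        retained = featurize_terminus("M" + "A" * 22, TerminusKind.N_MET_RETAINED)
        assert retained["w10_comp_M"] == 0.0
        assert retained["w10_comp_A"] == pytest.approx(1.0)
        assert retained["full_comp_M"] > 0.0          # whole peptide keeps it

    def test_pure_function(self):
        a = featurize_terminus("MKWLVNDEGHRASTYCQFIPKLM", TerminusKind.C)
        b = featurize_terminus("MKWLVNDEGHRASTYCQFIPKLM", TerminusKind.C)
        assert a == b

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            featurize_terminus("AXC", TerminusKind.C)


class TestCategorize:
    Q = (1.0, 2.0, 3.0, 4.0)

    @pytest.mark.parametrize("psi,expected", [
        (0.5, StabilityCategory.MOST_UNSTABLE),
        (1.5, StabilityCategory.UNSTABLE),
        (2.5, StabilityCategory.MEDIUM),
        (4.0, StabilityCategory.STABLE),       # right-closed at q80
        (4.01, StabilityCategory.MOST_STABLE),
    ])
    def test_bins(self, psi, expected):
        assert categorize_psi(psi, self.Q) is expected

    def test_partition_of_real_line(self, rng=None):
        import random
        r = random.Random(7)
        for _ in range(200):
            psi = r.uniform(-10, 10)
            cats = [categorize_psi(psi, self.Q)]
            assert len(cats) == 1 and isinstance(cats[0], StabilityCategory)

    def test_degenerate_quantiles_warn_medium(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert categorize_psi(5.0, (2.0,) * 4) is StabilityCategory.MEDIUM


class TestSynthesize:
    def test_reproducible_and_sized(self):
        a = synthesize_psi_dataset(100, "c", seed=3)
        b = synthesize_psi_dataset(100, "c", seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 100
        assert a["peptide"].str.len().eq(23).all()

    def test_met_retained_peptides_start_with_met(self):
        df = synthesize_psi_dataset(20, "n_met_retained", seed=1)
        assert df["peptide"].str.startswith("M").all()


class TestTraining:
    def test_defaults_match_documented_protocol(self):
        model = PSIRegressor()
        assert model.test_size == 0.1            # 90:10 split
        assert model.cv_folds == 5
        assert model.cv_validation_size == 0.2
        assert model.category_quantiles == (0.2, 0.4, 0.6, 0.8)

    def test_constant_target(self):
        df = synthesize_psi_dataset(100, "c", seed=2,
                                    effect_spec=lambda p, t: 3.0,
                                    noise_sigma=0.0)
        model = train_psi(df, run_cv=False, random_state=0)
        assert model.report_.rmse_test < 1e-6
        assert np.allclose(model.predict(list(df["peptide"][:5])), 3.0)

    def test_noiseless_gravy_recovery(self):
        df = synthesize_psi_dataset(800, "c", seed=5, noise_sigma=0.0)
        model = train_psi(df, run_cv=False, random_state=1)
        assert model.report_.r2_test >= 0.99

    def test_split_sizes_and_quantiles_monotone(self):
        df = synthesize_psi_dataset(500, "c", seed=4)
        model = train_psi(df, run_cv=False, random_state=1)
        rep = model.report_
        assert rep.n_train == 450 and rep.n_test == 50
        q = model.training_quantiles_
        assert list(q) == sorted(q)

    def test_mixed_termini_rejected(self):
        a = synthesize_psi_dataset(30, "c", seed=1)
        b = synthesize_psi_dataset(30, "n_met_cleaved", seed=1)
        with pytest.raises(ValueError, match="mixed"):
            train_psi(pd.concat([a, b], ignore_index=True))

    def test_insufficient_rows_rejected(self):
        df = synthesize_psi_dataset(20, "c", seed=1)
        with pytest.raises(ValueError, match="50"):
            train_psi(df, run_cv=False)

    def test_row_permutation_leaves_metrics_close(self):
        df = synthesize_psi_dataset(400, "c", seed=6)
        m1 = train_psi(df, run_cv=False, random_state=2)
        m2 = train_psi(df.sample(frac=1.0, random_state=9).reset_index(drop=True),
                       run_cv=False, random_state=2)
        assert m1.report_.r2_test == pytest.approx(m2.report_.r2_test, abs=0.05)

    def test_sklearn_params_roundtrip(self):
        model = PSIRegressor(terminus="c", max_iter=50)
        params = model.get_params()
        clone = PSIRegressor(**params)
        assert clone.get_params() == params
        model.set_params(max_iter=10)
        assert model.max_iter == 10


@pytest.fixture(scope="module")
def c_model():
    df = synthesize_psi_dataset(400, "c", seed=8)
    return train_psi(df, run_cv=False, random_state=3)


class TestPrediction:
    def test_category_from_training_quantiles(self, c_model):
        q = c_model.training_quantiles_
        median = (q[1] + q[2]) / 2
        assert categorize_psi(median, q) is StabilityCategory.MEDIUM
        assert categorize_psi(q[0] - 1, q) is StabilityCategory.MOST_UNSTABLE

    def test_predict_record_slices_terminal_23mer(self, c_model):
        rec = ProteinRecord(id="p", sequence="G" * 50 + "VLIVALIVLAVLIVALIVLAVLI")
        pred = predict_psi(c_model, rec)
        pep = terminal_peptide(rec, TerminusKind.C)
        assert pep.peptide == rec.sequence[-23:]
        assert pred.psi == pytest.approx(
            float(c_model.predict([pep.peptide])[0]))
        assert pred.terminus is TerminusKind.C

    def test_short_record_uses_available_residues(self, c_model):
        rec = ProteinRecord(id="p", sequence="VLIVALIVLA")     # length 10
        pred = predict_psi(c_model, rec)
        assert isinstance(pred.psi, float)

    def test_met_cleaved_slicing(self):
        rec = ProteinRecord(id="p", sequence="M" + "K" * 30)
        pep = terminal_peptide(rec, TerminusKind.N_MET_CLEAVED)
        assert pep.peptide == "K" * 23

    def test_prediction_order_matches_psi(self, c_model):
        # lower PSI <-> less stable category, by construction of the bins
        preds = c_model.predict_with_category(
            ["D" * 23, "V" * 23])           # very hydrophilic vs hydrophobic
        assert preds[0].psi < preds[1].psi

    def test_model_persistence_roundtrip(self, c_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(c_model, path)
        again = load_model(path)
        pep = "MKWLVNDEGHRASTYCQFIPKLM"[:23]
        assert float(again.predict([pep])[0]) == \
               pytest.approx(float(c_model.predict([pep])[0]))

    def test_gps_loader(self, tmp_path):
        p = tmp_path / "gps.tsv"
        p.write_text("protein_id\tterminus\tpeptide\tpsi\n"
                     "p1\tc\t" + "A" * 23 + "\t2.5\n")
        df = load_gps_table(p)
        assert df["psi"].iloc[0] == 2.5
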