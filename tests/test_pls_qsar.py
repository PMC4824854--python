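import numpy as np
import pandas as pd
import pytest

from calpcleave import (
    AMINO_ACIDS,
    DescriptorTable,
    Peptide,
    PlsQsarModel,
    backward_select_pls,
    build_window,
    design_matrix,
    evaluate_regression,
    exclude_outliers_and_refit,
    fit_pls,
    position_contribution,
    predict_kcat_km,
    score_subsequence,
)
from calpcleave.pls_qsar import _nipals_pls1

from .conftest import make_table, matrix_from_array


class TestNipalsCore:
    def test_noiseless_single_feature_recovered_exactly(self):
        x = np.linspace(0, 10, 20)[:, None]
        y = 3.25 * x[:, 0] + 40.0
        fm = matrix_from_array(x, [("P2", "D")], response=y)
        m = fit_pls(fm, n_components=1)
        assert m.coefficients[0] == pytest.approx(3.25, rel=1e-6)
        assert m.intercept == pytest.approx(40.0, rel=1e-6)

    def test_full_component_pls_equals_least_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.normal(size=(30, 4)) @ np.diag([1, 2, 0.5, 3])
            y = rng.normal(size=30)
            coef, icpt, _ = _nipals_pls1(X, y, 4)
            A = np.c_[X, np.ones(30)]
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            assert np.max(np.abs(coef - beta[:4])) < 1e-8
            assert abs(icpt - beta[4]) < 1e-8

    def test_matches_sklearn_pls_at_reduced_components(self):
        """Independent cross-check against the reference PLS
        implementation for every component count below full rank."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=40)
        for k in (1, 2, 3, 4, 5):
            coef, icpt, _ = _nipals_pls1(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=True).fit(X, y)
            ref_coef = ref.coef_.ravel()
            ref_icpt = float(np.ravel(ref.intercept_)[0]
                             - ref._x_mean @ ref_coef)
            np.testing.assert_allclose(coef, ref_coef, atol=1e-8)
            assert icpt == pytest.approx(ref_icpt, abs=1e-8)

    def test_planted_coefficient_recovery_under_noise(self):
        """n=119 with 10% multiplicative noise: signs always recovered,
        coefficients within 15% relative error (10/10 seeds)."""
        true = np.array([7.99, -11.7, 62.6, -8.60, 120.0, -30.5, -11.5, 1.04])
        # descriptor scales sized so each feature moves kcat/Km by a
        # comparable ~100 M^-1 s^-1, as the tabulated per-descriptor
        # deltas do
        col_sd = 100.0 / np.abs(true)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(119, 8)) * col_sd
            y_clean = X @ true + 800.0
            # noise sd = 10% of the response sd
            y = y_clean + rng.normal(0, 0.1 * y_clean.std(), 119)
            cols = [(f"P{i+1}", "D") for i in range(8)]
            m = fit_pls(matrix_from_array(X, cols, response=y),
                        n_components=8)
            assert np.all(np.sign(m.coefficients) == np.sign(true))
            rel = np.abs(m.coefficients - true) / np.abs(true)
            assert np.max(rel) < 0.15

    def test_rank_deficient_rejected(self):
        fm = matrix_from_array(np.ones((10, 2)), [("P1", "A"), ("P2", "B")],
                               response=np.ones(10))
        with pytest.raises(ValueError):
            fit_pls(fm, n_components=2)


class TestOutliers:
    def _clean_fit(self, seed=2, n=50):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = X @ np.array([5.0, -3.0, 2.0]) + 100
        cols = [("P1", "A"), ("P2", "B"), ("P3", "C")]
        return X, y, cols

    def test_clean_data_no_outliers(self):
        X, y, cols = self._clean_fit()
        y = y + np.random.default_rng(3).normal(0, 1.0, len(y))
        fm = matrix_from_array(X, cols, response=y)
        m = fit_pls(fm, n_components=3)
        m2 = exclude_outliers_and_refit(m, fm)
        assert m2.excluded_outliers == []
        np.testing.assert_allclose(m2.coefficients, m.coefficients)

    def test_planted_outlier_flagged_exactly(self):
        X, y, cols = self._clean_fit()
        rng = np.random.default_rng(4)
        y = y + rng.normal(0, 1.0, len(y))
        y[17] += 10 * y.std()
        fm = matrix_from_array(X, cols, response=y)
        m = fit_pls(fm, n_components=3)
        m2 = exclude_outliers_and_refit(m, fm)
        assert m2.excluded_outliers == ["w17"]

    def test_mass_flagging_refused(self):
        X, y, cols = self._clean_fit(n=20)
        rng = np.random.default_rng(5)
        y = rng.choice([-1e4, 1e4], 20) + y * 0  # all rows extreme
        # a bimodal response leaves >20% of rows far from any fit
        fm = matrix_from_array(X, cols, response=y + rng.normal(0, 1, 20))
        m = fit_pls(fm, n_components=3)
        try:
            m2 = exclude_outliers_and_refit(m, fm, z_threshold=0.1)
        except ValueError as err:
            assert "refusing" in str(err)
        else:  # pragma: no cover - must not happen
            pytest.fail("mass flagging was not refused")


class TestBackwardSelectionPls:
    def test_single_perfect_predictor(self):
        x = np.linspace(0, 1, 30)[:, None]
        fm = matrix_from_array(x, [("P2", "D")], response=5 * x[:, 0])
        traj = backward_select_pls(fm, floor=0.6)
        assert len(traj.steps) == 1 and traj.floor_met

    def test_planted_signal_recovered_across_seeds(self):
        """Three equal planted signals sized so that any two explain
        ~50% of the variance but all three explain ~75%: the smallest
        feature set clearing the Xr^2 > 0.6 floor must carry all
        three."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 6))
            y = X[:, :3] @ np.array([1.0, -1.0, 1.0]) + rng.normal(0, 1.0, 80)
            cols = [(f"P{i+1}", f"D{i+1}") for i in range(6)]
            traj = backward_select_pls(
                matrix_from_array(X, cols, response=y),
                floor=0.6, n_components=3)
            chosen = {c[1] for c in traj.chosen_features}
            if {"D1", "D2", "D3"} <= chosen and len(chosen) <= 4:
                hits += 1
        assert hits >= 8


class TestPredictionAndContribution:
    @pytest.fixture
    def paper_style_model(self, toy_tables):
        """Single- and paired-position features with fixed coefficients."""
        return PlsQsarModel(
            features=[(("P10",), "SCALE1"),
                      (("P2", "P1"), "SCALE2"),
                      (("P3p",), "HYDRO")],
            coefficients=np.array([7.99, -11.7, 62.6]),
            intercept=150.0,
            tables=toy_tables,
        )

    def test_prediction_is_linear_and_intercept_free_differences(
            self, paper_style_model, toy_tables):
        w1 = build_window(Peptide("a", "ACDEFGHIKLMNPQRSTVWY"), 10)
        w2 = build_window(Peptide("b", "YWVTSRQPNMLKIHGFEDCA"), 10)
        d1 = predict_kcat_km(paper_style_model, w1) - predict_kcat_km(
            paper_style_model, w2)
        shifted = PlsQsarModel(
            features=paper_style_model.features,
            coefficients=paper_style_model.coefficients,
            intercept=paper_style_model.intercept + 1234.5,
            tables=toy_tables,
        )
        d2 = predict_kcat_km(shifted, w1) - predict_kcat_km(shifted, w2)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_paired_feature_sums_both_member_positions(
            self, paper_style_model, toy_tables):
        w = build_window(Peptide("a", "ACDEFGHIKLMNPQRSTVWY"), 10)
        s1, s2 = toy_tables["SCALE1"], toy_tables["SCALE2"]
        hy = toy_tables["HYDRO"]
        expected = (
            150.0
            + 7.99 * s1.values[w.residues["P10"]]
            - 11.7 * (s2.values[w.residues["P2"]]
                      + s2.values[w.residues["P1"]])
            + 62.6 * hy.values[w.residues["P3p"]]
        )
        assert predict_kcat_km(paper_style_model, w) == pytest.approx(expected)

    def test_missing_single_position_feature_raises(
            self, paper_style_model):
        w = build_window(Peptide("a", "ACDEFGHIKLMNPQRSTVWY"), 2)  # P10 gone
        with pytest.raises(ValueError, match="missing"):
            predict_kcat_km(paper_style_model, w)

    def test_contribution_matches_brute_force(self, paper_style_model,
                                              toy_tables):
        prof = position_contribution(paper_style_model, "P2")
        s2 = toy_tables["SCALE2"]
        mean2 = np.mean([s2.values[a] for a in AMINO_ACIDS])
        for res in AMINO_ACIDS:
            expected = -11.7 * (s2.values[res] + mean2)
            assert prof.per_residue_delta[res] == pytest.approx(expected)
        assert prof.range >= 0

    def test_contribution_sum_identity_for_unpaired_model(self, toy_tables):
        """Summing per-position contributions plus intercept equals the
        full prediction when no feature is paired."""
        model = PlsQsarModel(
            features=[(("P2",), "HYDRO"), (("P1",), "SCALE1"),
                      (("P3p",), "SCALE2")],
            coefficients=np.array([3.0, -2.0, 1.5]),
            intercept=80.0,
            tables=toy_tables,
        )
        w = build_window(Peptide("a", "ACDEFGHIKLMNPQRSTVWY"), 10)
        total = model.intercept
        for pos in ("P2", "P1", "P3p"):
            prof = position_contribution(model, pos)
            total += prof.per_residue_delta[w.residues[pos]]
        assert total == pytest.approx(predict_kcat_km(model, w))

    def test_constant_table_flat_profile(self):
        const = DescriptorTable(id="C", values={a: 2.0 for a in AMINO_ACIDS})
        model = PlsQsarModel(features=[(("P2",), "C")],
                             coefficients=np.array([10.0]), intercept=0.0,
                             tables={"C": const})
        prof = position_contribution(model, "P2")
        assert prof.range == 0.0

    def test_position_not_in_model_raises(self, paper_style_model):
        with pytest.raises(ValueError, match="not in the model"):
            position_contribution(paper_style_model, "P7")


class TestSubsequenceScoring:
    def test_additive_per_position_argmax_equals_exhaustive_max(
            self, toy_tables):
        """With additive features the best subsequence decomposes per
        position, so composing per-position argmaxes equals the
        exhaustive optimum (checked on a reduced alphabet)."""
        model = PlsQsarModel(
            features=[(("P2",), "HYDRO"), (("P1",), "SCALE1"),
                      (("P1p",), "SCALE2")],
            coefficients=np.array([3.0, -2.0, 1.5]),
            intercept=50.0,
            tables=toy_tables,
        )
        rng = np.random.default_rng(6)
        alphabet = list(rng.choice(list(AMINO_ACIDS), 6, replace=False))
        positions = ["P2", "P1", "P1p"]
        best_exhaustive = -np.inf
        for a in alphabet:
            for b in alphabet:
                for c in alphabet:
                    s = score_subsequence(
                        model, {"P2": a, "P1": b, "P1p": c}, positions)
                    best_exhaustive = max(best_exhaustive, s)
        composed = {}
        for pos in positions:
            prof = position_contribution(model, pos)
            composed[pos] = max(
                (r for r in alphabet), key=lambda r: prof.per_residue_delta[r])
        assert score_subsequence(model, composed, positions) == pytest.approx(
            best_exhaustive)

    def test_out_of_range_features_marginalized(self, toy_tables):
        model = PlsQsarModel(
            features=[(("P10",), "SCALE1"), (("P1",), "HYDRO")],
            coefficients=np.array([2.0, 4.0]),
            intercept=10.0,
            tables=toy_tables,
        )
        s = score_subsequence(model, {"P1": "L"}, ["P1"])
        mean1 = np.mean([toy_tables["SCALE1"].values[a] for a in AMINO_ACIDS])
        expected = 10.0 + 2.0 * mean1 + 4.0 * toy_tables["HYDRO"].values["L"]
        assert s == pytest.approx(expected)

    def test_range_without_model_features_raises(self, toy_tables):
        model = PlsQsarModel(features=[(("P10",), "SCALE1")],
                             coefficients=np.array([1.0]), intercept=0.0,
                             tables=toy_tables)
        with pytest.raises(ValueError, match="range excludes"):
            score_subsequence(model, {"P1": "A"}, ["P1"])


class TestEvaluateRegression:
    def test_identity_predictions(self):
        y = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        r = evaluate_regression(y, y)
        assert r["r"] == pytest.approx(1.0)
        assert r["slope"] == pytest.approx(1.0)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_five_point_toy_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([2.0, 3.5, 4.0, 6.5, 7.0])
        r = evaluate_regression(yhat, x)
        # hand values: slope = cov/var = 13/10 = 1.3, intercept = 0.7
        assert r["slope"] == pytest.approx(1.3)
        assert r["intercept"] == pytest.approx(0.7)
        assert r["r"] == pytest.approx(
            np.corrcoef(x, yhat)[0, 1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_design_matrix_json_round_trip(self, toy_tables):
        windows = [build_window(Peptide("a", "ACDEFGHIKLMNPQRSTVWY"), b)
                   for b in (8, 9, 10, 11, 12)]
        feats = [(("P2", "P1"), "SCALE2"), (("P1p",), "HYDRO")]
        rng = np.random.default_rng(0)
        fm = design_matrix(windows, feats, toy_tables,
                           response={w.id: float(100 + 10 * rng.random())
                                     for w in windows})
        m = fit_pls(fm, n_components=2, tables=toy_tables)
        m2 = PlsQsarModel.from_json(m.to_json())
        np.testing.assert_allclose(m.coefficients, m2.coefficients)
        assert m.features == m2.features
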