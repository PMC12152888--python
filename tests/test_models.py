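"""Transfer-model fitting, prediction, metrics and correlations."""

import numpy as np
import pandas as pd
import pytest

import cdwheat as cw
from cdwheat.equations import DomainError, MissingFeatureError

from conftest import make_frame


class TestPrediction:
    def test_published_m1_values(self):
        m1 = cw.builtin_model("M1")
        assert float(m1.predict({"cd_total": 0.488})) == pytest.approx(
            0.100, abs=5e-4)
        assert float(m1.predict({"cd_total": 1.0})) == pytest.approx(
            10 ** -0.718, rel=1e-12)

    def test_zero_model_predicts_unity(self):
        model = cw.TransferModel(
            id="null", terms=(cw.Term("cd_total", "log10", 0.0),),
            intercept=0.0)
        assert float(model.predict({"cd_total": 123.0})) == 1.0

    def test_bcf_model_predicts_product(self):
        m3 = cw.builtin_model("M3")
        ph, cd = 6.0, 2.0
        bcf = 0.014 * ph ** 2 - 0.236 * ph + 1.113
        assert float(m3.predict({"ph": ph, "cd_total": cd})) == pytest.approx(
            bcf * cd, rel=1e-12)

    def test_missing_feature_is_named(self):
        m2 = cw.builtin_model("M2")
        with pytest.raises(MissingFeatureError, match="cec"):
            m2.predict({"cd_total": 1.0, "ph": 6.0})

    def test_nonpositive_under_log_raises(self):
        m1 = cw.builtin_model("M1")
        with pytest.raises(DomainError, match="cd_total"):
            m1.predict({"cd_total": -1.0})

    def test_dataframe_prediction_matches_linear_predictor(self,
                                                           default_dataset):
        m2 = cw.builtin_model("M2")
        pred = m2.predict(default_dataset.df)
        np.testing.assert_allclose(
            pred, 10.0 ** m2.linear_predictor(default_dataset.df), rtol=0)

    def test_yaml_roundtrip(self, tmp_path):
        m2 = cw.builtin_model("M2")
        path = tmp_path / "m2.yaml"
        m2.to_yaml(path)
        assert cw.TransferModel.from_yaml(path) == m2


class TestFitting:
    def test_mixed_cd_pools_refused(self, default_dataset):
        with pytest.raises(ValueError, match="pool"):
            cw.fit_transfer_model(default_dataset, ["cd_total", "cd_cacl2"])

    def test_two_points_one_feature_interpolates(self):
        df = make_frame(2, cd_total=[1.0, 10.0], cd_wheat=[0.1, 0.5])
        res = cw.fit_transfer_model(df, ["cd_total"])
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.predict(df), [0.1, 0.5], rtol=1e-9)

    def test_collinear_design_rejected(self):
        df = make_frame(10, ph=np.linspace(5, 7, 10),
                        cd_total=np.linspace(1, 2, 10),
                        cd_wheat=np.linspace(0.1, 0.3, 10))
        df["cec"] = 2.0 * df["ph"]  # exactly collinear pair
        with pytest.raises(ValueError, match="collinear"):
            cw.fit_transfer_model(df, ["ph", "cec"])

    def test_fitted_values_match_least_squares_solution(self, default_dataset):
        res = cw.fit_transfer_model(default_dataset, ["cd_total", "ph", "cec"])
        # the exported frozen equation reproduces the OLS fitted values
        df = default_dataset.df
        pred = np.log10(res.predict(df))
        X = np.column_stack([np.ones(len(df)), np.log10(df["cd_total"]),
                             df["ph"], df["cec"]])
        beta, *_ = np.linalg.lstsq(X, np.log10(df["cd_wheat"]), rcond=None)
        np.testing.assert_allclose(pred, X @ beta, rtol=0, atol=1e-10)

    def test_convergence_with_noise_and_sample_size(self):
        """Estimation error shrinks as noise -> 0 and as n grows."""
        truth = cw.WheatResponse(noise_sd=0.25)
        def err(n, noise_sd, seed):
            cfg = cw.SyntheticConfig(
                n=n, seed=seed,
                wheat=cw.WheatResponse(noise_sd=noise_sd))
            res = cw.fit_transfer_model(cw.generate_dataset(cfg),
                                        ["cd_total", "ph", "cec"])
            return abs(res.params["cd_total"] - truth.coef_log10cd)
        assert err(311, 0.01, 1) < err(311, 0.5, 1)
        errs_small = np.mean([err(100, 0.25, s) for s in range(8)])
        errs_big = np.mean([err(3000, 0.25, s) for s in range(8)])
        assert errs_big < errs_small

    def test_summary_lists_terms(self, default_dataset):
        res = cw.fit_transfer_model(default_dataset, ["cd_total", "ph"],
                                    model_id="demo")
        text = res.summary()
        assert "log10(cd_total)" in text and "demo" in text
        assert f"n = {res.nobs}" in text


class TestBcfQuadratic:
    def test_exact_recovery(self):
        ph = np.linspace(4.0, 8.5, 40)
        bcf = 0.014 * ph ** 2 - 0.236 * ph + 1.113
        df = make_frame(40, ph=ph, cd_total=1.0, cd_wheat=bcf)
        fit = cw.fit_bcf_quadratic(df)
        assert fit.model.a == pytest.approx(0.014, abs=1e-9)
        assert fit.model.b == pytest.approx(-0.236, abs=1e-9)
        assert fit.model.c == pytest.approx(1.113, abs=1e-9)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_constant_bcf_collapses_to_mean(self):
        df = make_frame(10, ph=np.linspace(4, 8, 10), cd_total=1.0,
                        cd_wheat=0.25)
        fit = cw.fit_bcf_quadratic(df)
        assert fit.model.a == pytest.approx(0.0, abs=1e-10)
        assert fit.model.b == pytest.approx(0.0, abs=1e-10)
        assert fit.model.c == pytest.approx(0.25, abs=1e-10)

    def test_needs_four_distinct_ph(self):
        df = make_frame(6, ph=[4, 4, 5, 5, 6, 6], cd_wheat=0.2)
        with pytest.raises(ValueError, match="distinct pH"):
            cw.fit_bcf_quadratic(df)

    def test_fitted_curve_decreases_on_acid_range(self, default_dataset):
        fit = cw.fit_bcf_quadratic(default_dataset)
        grid = np.linspace(4.0, 7.0, 50)
        vals = fit.model.bcf(grid)
        assert np.all(np.diff(vals) < 0)


class TestEvaluation:
    def test_perfect_predictions(self, noiseless_dataset):
        m2 = cw.builtin_model("M2")
        tr, te = cw.split_dataset(noiseless_dataset,
                                  cw.SplitSpec(n_repeats=1, seed=0))[0]
        m = cw.evaluate_model(m2, tr, te)
        assert m.r2_train == pytest.approx(1.0, abs=1e-12)
        assert m.r2_test == pytest.approx(1.0, abs=1e-12)
        assert m.rmse_test == pytest.approx(0.0, abs=1e-12)
        assert m.mae_test == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_residuals_closed_form(self):
        m1 = cw.builtin_model("M1")
        pred = float(m1.predict({"cd_total": 1.0}))
        test = make_frame(2, cd_total=1.0,
                          cd_wheat=[pred * 10 ** 0.1, pred * 10 ** -0.1])
        m = cw.evaluate_model(m1, test, test)
        assert m.rmse_test == pytest.approx(0.1, rel=1e-9)
        assert m.mae_test == pytest.approx(0.1, rel=1e-9)

    def test_constant_predictor_r2_not_clamped(self, default_dataset):
        const = cw.TransferModel(
            id="const", terms=(cw.Term("cd_total", "log10", 0.0),),
            intercept=np.log10(0.3))
        tr, te = cw.split_dataset(default_dataset,
                                  cw.SplitSpec(n_repeats=1, seed=0))[0]
        m = cw.evaluate_model(const, tr, te)
        assert m.r2_test <= 0

    def test_rmse_dominates_mae(self, default_dataset):
        tr, te = cw.split_dataset(default_dataset,
                                  cw.SplitSpec(n_repeats=1, seed=2))[0]
        for mid in ("M1", "M2", "M3", "M4", "M5"):
            m = cw.evaluate_model(cw.builtin_model(mid), tr, te)
            assert m.rmse_test >= m.mae_test >= 0

    def test_empty_test_set_rejected(self, default_dataset):
        empty = default_dataset.df.iloc[:0]
        with pytest.raises(ValueError, match="empty test"):
            cw.evaluate_model(cw.builtin_model("M1"), default_dataset.df,
                              empty)


class TestCorrelations:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        cd = 10 ** rng.normal(0, 0.4, 50)
        df = make_frame(50, cd_total=cd, cd_wheat=2.0 * cd)
        out = cw.pearson_correlations(df)
        r = out.r.loc["log10_cd_total", "log10_cd_wheat"]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert out.p.loc["log10_cd_total", "log10_cd_wheat"] < 1e-10

    def test_zero_variance_column_flagged(self):
        df = make_frame(20, cd_total=np.linspace(1, 2, 20),
                        cd_wheat=np.linspace(0.1, 0.4, 20))
        out = cw.pearson_correlations(df)
        assert "ph" in out.degenerate
        assert np.isnan(out.r.loc["ph", "log10_cd_wheat"])

    def test_negative_ph_bcf_relation_in_noiseless_data(self,
                                                        noiseless_dataset):
        out = cw.pearson_correlations(noiseless_dataset)
        assert out.r.loc["ph", "bcf"] < 0
        assert out.r.loc["log10_cd_total", "log10_cd_wheat"] > 0

    def test_independent_columns_near_zero(self, default_dataset):
        # clay and SOM never enter the response; at n=311 their correlation
        # with grain Cd should be weak
        big = cw.generate_dataset(cw.SyntheticConfig(n=1000, seed=13))
        out = cw.pearson_correlations(big)
        assert abs(out.r.loc["clay", "log10_cd_wheat"]) < 0.1
        assert abs(out.r.loc["som", "log10_cd_wheat"]) < 0.1

    def test_needs_three_records(self):
        with pytest.raises(ValueError):
            cw.pearson_correlations(make_frame(2))
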