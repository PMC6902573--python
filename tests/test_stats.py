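"""Statistical stage: summary tests, regression, stepwise selection,
prediction, and observer reliability."""

import numpy as np
import pandas as pd
import pytest

from femver.errors import DegenerateGeometryError, IncompleteRecordError
from femver.morphometry import MorphometryRecord
from femver.stats import (
    PUBLISHED_CF_EQUATION,
    GroupSummary,
    PredictionResult,
    RegressionFit,
    assign_group,
    chi2_contingency,
    ols_fit,
    pearson_r,
    pooled_t_from_raw,
    pooled_t_from_summary,
    predict_stem_anteversion,
    prediction_errors,
    reliability,
    stepwise_forward,
)


class TestGrouping:
    def test_assign(self):
        assert assign_group(MorphometryRecord("a", cf_present_lfn=True)) == "CF"
        assert assign_group(MorphometryRecord("b", cf_present_lfn=False)) == "nonCF"

    def test_missing_flag(self):
        with pytest.raises(IncompleteRecordError):
            assign_group({"cf_present_lfn": None})


class TestPooledT:
    def test_published_group_contrast(self):
        """FA-MFN group summaries reproduce the published pooled t."""
        t, df, p = pooled_t_from_summary(GroupSummary(13, 33.5, 13.1), GroupSummary(21, 18.5, 9.5))
        assert t == pytest.approx(3.870, abs=0.01)
        assert df == 32
        assert p < 0.001

    def test_identical_summaries(self):
        g = GroupSummary(10, 5.0, 2.0)
        t, _, p = pooled_t_from_summary(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        t, _, p = pooled_t_from_summary(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))
        assert np.isinf(t) and p == 0.0

    def test_raw_agrees_with_summary(self):
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(10, 3, 21), rng.normal(12, 4, 13)
        t_raw, df_raw, p_raw = pooled_t_from_raw(x1, x2)
        t_sum, df_sum, p_sum = pooled_t_from_summary(
            GroupSummary.from_values(x1), GroupSummary.from_values(x2)
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        assert p_raw == pytest.approx(p_sum, abs=1e-12)


class TestChi2:
    def test_crowe_table(self):
        stat, df, p = chi2_contingency([[18, 2, 1], [4, 6, 3]])
        assert stat == pytest.approx(10.63, abs=0.05)
        assert df == 2
        assert p == pytest.approx(0.005, abs=0.002)

    def test_proportional_rows(self):
        stat, _, p = chi2_contingency([[10, 20, 30], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2(self):
        stat, df, _ = chi2_contingency([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0) and df == 1

    def test_zero_margin(self):
        with pytest.raises(DegenerateGeometryError):
            chi2_contingency([[5, 0], [3, 0]])


class TestPearson:
    def test_perfect(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_zero_variance(self):
        with pytest.raises(DegenerateGeometryError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestOLS:
    def test_noiseless_single_predictor(self):
        x = np.linspace(20, 60, 13)
        y = 0.749 * x - 1.433
        fit = ols_fit({"fa_lfn_deg": x}, y)
        assert fit.coefficients[0] == pytest.approx(0.749, abs=1e-12)
        assert fit.intercept == pytest.approx(-1.433, abs=1e-10)
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        x = np.linspace(0, 1, 10)
        fit = ols_fit({"x": x}, np.full(10, 3.0))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.R2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_against_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        fit = ols_fit({f"x{i}": X[:, i] for i in range(3)}, y)
        D = np.column_stack([np.ones(15), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.coefficients == pytest.approx(beta[1:], abs=1e-9)

    def test_collinearity(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateGeometryError):
            ols_fit({"a": x, "b": 2 * x}, x)

    def test_r2_invariant(self):
        with pytest.raises(ValueError):
            RegressionFit(["a"], [1.0], 0.0, R=0.8, R2=0.5, coefficient_p=[0.1], n=10)


class TestStepwise:
    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        cand = {f"x{i}": rng.normal(size=21) for i in range(4)}
        y = rng.normal(size=21)
        fit = stepwise_forward(cand, y)
        assert fit.predictors == []
        assert fit.intercept == pytest.approx(float(np.mean(y)))

    def test_alpha_one_enters_all(self):
        rng = np.random.default_rng(1)
        cand = {f"x{i}": rng.normal(size=25) for i in range(3)}
        y = rng.normal(size=25)
        fit = stepwise_forward(cand, y, alpha_enter=1.0)
        assert sorted(fit.predictors) == ["x0", "x1", "x2"]

    def test_noiseless_recovers_generating_model(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        noise = rng.normal(size=30)  # an irrelevant candidate
        y = 2.0 * x1 - 1.0 * x2 + 0.5
        fit = stepwise_forward({"x1": x1, "x2": x2, "noise": noise}, y)
        assert set(fit.predictors) == {"x1", "x2"}
        coefs = dict(zip(fit.predictors, fit.coefficients))
        assert coefs["x1"] == pytest.approx(2.0, abs=1e-9)
        assert coefs["x2"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.5, abs=1e-9)


class TestPrediction:
    def test_group_mean_centroids(self):
        """The published equations evaluated at the group means return the
        group mean stem anteversions (least-squares centroid property)."""
        cf = predict_stem_anteversion(
            {"hip_id": "h", "cf_present_lfn": True, "fa_clt_deg": 52.0, "cf_lfn_deg": 35.9}
        )
        assert cf.predicted_anteversion == pytest.approx(26.7, abs=0.1)
        ncf = predict_stem_anteversion(
            {"hip_id": "h", "cf_present_lfn": False, "fa_lfn_deg": 39.2}
        )
        assert ncf.predicted_anteversion == pytest.approx(27.9, abs=0.1)
        assert ncf.equation_used == "nonCF"

    def test_zero_predictors_give_intercept(self):
        res = predict_stem_anteversion(
            {"hip_id": "h", "cf_present_lfn": True, "fa_clt_deg": 0.0, "cf_lfn_deg": 0.0}
        )
        assert res.predicted_anteversion == pytest.approx(PUBLISHED_CF_EQUATION.intercept)

    def test_missing_predictor(self):
        with pytest.raises(IncompleteRecordError):
            predict_stem_anteversion({"hip_id": "h", "cf_present_lfn": True, "fa_clt_deg": 50.0})

    def test_absolute_error(self):
        res = predict_stem_anteversion(
            {
                "hip_id": "h",
                "cf_present_lfn": False,
                "fa_lfn_deg": 39.2,
                "stem_anteversion_deg": 30.0,
            }
        )
        assert res.absolute_error == pytest.approx(abs(res.predicted_anteversion - 30.0))


class TestPredictionErrors:
    def test_exact_predictions(self):
        results = [
            PredictionResult("a", 10.0, "CF", observed_anteversion=10.0),
            PredictionResult("b", 20.0, "CF", observed_anteversion=20.0),
        ]
        out = prediction_errors(results)
        assert out["CF"]["mean"] == 0.0 and out["CF"]["sd"] == 0.0

    def test_symmetric_residuals(self):
        results = [
            PredictionResult(str(i), 10.0 + r, "nonCF", observed_anteversion=10.0)
            for i, r in enumerate([3, -3, 3, -3])
        ]
        out = prediction_errors(results)
        assert out["nonCF"]["mean"] == pytest.approx(3.0)
        assert out["nonCF"]["sd"] == pytest.approx(0.0)

    def test_no_observed(self):
        with pytest.raises(ValueError):
            prediction_errors([PredictionResult("a", 5.0, "CF")])


class TestReliability:
    @staticmethod
    def landmark_models(n=10, seed=0):
        """Cheap models whose measured quantities derive from landmarks only."""
        from femver.geometry import SurfaceModel

        rng = np.random.default_rng(seed)
        models = []
        for _ in range(n):
            h = rng.uniform(60, 90)
            ang = np.radians(rng.uniform(-40, 40))
            lm = {
                "GT": np.array([0.0, 0.0, 0.0]),
                "CLT": np.array([0.0, 0.0, -h]),
                "MED_POST_CONDYLE": 20 * np.array([np.sin(ang), np.cos(ang), 0.0]),
                "LAT_POST_CONDYLE": -20 * np.array([np.sin(ang), np.cos(ang), 0.0]),
            }
            models.append(
                SurfaceModel(np.eye(4, 3) * 100, [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]], lm)
            )
        return models

    @staticmethod
    def measurer(model):
        d = model.landmark("LAT_POST_CONDYLE") - model.landmark("MED_POST_CONDYLE")
        return {
            "pca_angle": float(np.degrees(np.arctan2(d[0], d[1]))),
            "H": float(model.landmark("GT")[2] - model.landmark("CLT")[2]),
        }

    def test_zero_jitter_is_perfect(self):
        intra, inter = reliability(self.measurer, self.landmark_models(), jitter_sd=0.0)
        assert all(r == pytest.approx(1.0) for r in intra.values())
        assert all(r == pytest.approx(1.0) for r in inter.values())

    def test_small_jitter_high_reliability(self):
        intra, inter = reliability(
            self.measurer, self.landmark_models(30), jitter_sd=1.0, seed=1
        )
        assert all(r > 0.8 for r in intra.values())
        assert all(r > 0.8 for r in inter.values())

    def test_monotone_degradation(self):
        models = self.landmark_models(30)
        intra1, _ = reliability(self.measurer, models, jitter_sd=1.0, seed=2)
        intra20, _ = reliability(self.measurer, models, jitter_sd=20.0, seed=2)
        assert np.mean(list(intra20.values())) < np.mean(list(intra1.values()))

    def test_too_few_models(self):
        with pytest.raises(ValueError):
            reliability(self.measurer, self.landmark_models(2))


class TestModelObjects:
    def test_fit_and_summary(self):
        from femver.model import StemAnteversionModel
        from femver.synthetic import CohortSpec, generate_cohort

        df = generate_cohort(CohortSpec(seed=42))
        res = StemAnteversionModel(df).fit()
        assert "CF" in res.group_fits and "nonCF" in res.group_fits
        text = res.summary()
        assert "stepwise" in text and "pooled t" in text
        report = res.to_report()
        assert set(report["groups"]) == {"CF", "nonCF"}
        # self-consistency: report errors equal recomputed in-sample errors
        preds = res.predict(df)
        errs = [p.absolute_error for p in preds if p.equation_used == "CF"]
        assert np.mean(errs) == pytest.approx(res.prediction_error_summary["CF"]["mean"])

    def test_schema_validation(self):
        from femver.errors import SchemaError
        from femver.model import StemAnteversionModel

        with pytest.raises(SchemaError):
            StemAnteversionModel(pd.DataFrame({"hip_id": ["a"]}))
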