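"""Model-zoo tests: design matrices, the three estimators' fit/predict
contracts, and their statistical behaviour on data with known structure."""

import numpy as np
import pandas as pd
import pytest

import costsim as cs
from costsim.models import ModelSpec, build_design


class TestDesignMatrix:
    def test_main_effects_column_count(self, gamma_data):
        X = build_design(gamma_data.covariates, ModelSpec("gamma_glm", "main_effects"))
        # intercept + 6 linear + 4 dummies + z1 + z2 + x8
        assert X.shape[1] == 14

    def test_correct_spec_column_count(self, gamma_data):
        X = build_design(gamma_data.covariates, ModelSpec("gamma_glm", "correct"))
        # 14 - 3 linear nonlinear terms + 3x3 spline columns + interaction
        assert X.shape[1] == 21
        assert any("bs(z1" in c for c in X.columns)
        assert any(":" in c for c in X.columns)

    def test_rf_design_is_raw_covariates(self, gamma_data):
        X = build_design(gamma_data.covariates, ModelSpec("rf", "correct"))
        assert list(X.columns) == list(gamma_data.covariates.columns)

    def test_missing_column_errors(self, gamma_data):
        with pytest.raises(KeyError):
            build_design(gamma_data.covariates.drop(columns=["x4"]), ModelSpec("plaqr"))


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(family="ols"), dict(family="rf", specification="full"),
         dict(family="plaqr", tau=0.0), dict(family="rf", rf_ntree=0)],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelSpec(**kw)


class TestGammaGLM:
    def test_intercept_recovery_with_null_covariates(self):
        # covariates carry no signal; the fitted intercept estimates log E[cost]
        rng = np.random.default_rng(120)
        cov = cs.generate_covariates(4000, seed=12)
        cost = rng.gamma(48.0, np.exp(11.05) / 48.0, 4000)
        res = cs.fit_gamma_glm(cov.assign(cost=cost), spec=ModelSpec("gamma_glm", "main_effects"))
        assert res.converged
        z = (res.params["Intercept"] - 11.05) / res.bse["Intercept"]
        assert abs(z) < 3

    def test_requires_positive_costs(self, gamma_data):
        frame = gamma_data.frame.copy()
        frame.loc[0, "cost"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            cs.fit_gamma_glm(frame)

    def test_predictions_positive_and_shaped(self, gamma_data):
        res = cs.fit_gamma_glm(gamma_data)
        pred = res.predict(gamma_data.covariates)
        assert pred.shape == (gamma_data.n,)
        assert (pred > 0).all()
        assert "Intercept" in res.summary()


class TestPLAQR:
    def test_constant_outcome_predicts_the_constant(self):
        cov = cs.generate_covariates(120, seed=3)
        res = cs.fit_plaqr(cov.assign(cost=7.0), spec=ModelSpec("plaqr", "main_effects"))
        assert np.allclose(res.predict(cov), 7.0, atol=1e-8)

    def test_symmetric_noise_recovers_location(self):
        rng = np.random.default_rng(400)
        cov = cs.generate_covariates(5000, seed=4)
        cost = 5.0 + rng.uniform(-1, 1, 5000)
        res = cs.fit_plaqr(cov.assign(cost=cost), spec=ModelSpec("plaqr", "main_effects"))
        pred = res.predict(cov)
        # the covariates carry no signal, so the fitted median surface is flat at 5
        assert np.mean(pred) == pytest.approx(5.0, abs=0.05)
        assert np.std(pred) < 0.2

    def test_check_loss_optimality(self):
        data = cs.simulate_dataset(300, "gamma", seed=5)
        spec = ModelSpec("plaqr", "main_effects")
        res = cs.fit_plaqr(data, spec=spec)
        X = np.asarray(build_design(data.covariates, spec))
        y = data.cost

        def check_loss(beta):
            e = y - X @ beta
            return np.mean(np.where(e >= 0, 0.5 * e, -0.5 * e))

        beta = res.params.to_numpy()
        fit_loss = check_loss(beta)
        assert fit_loss <= check_loss(np.zeros_like(beta))
        for j in range(beta.size):
            for step in (1e-3, -1e-3):
                bp = beta.copy()
                bp[j] += step
                assert check_loss(bp) >= fit_loss - 1e-6 * fit_loss

    def test_collinear_design_raises_diagnostic(self):
        cov = cs.generate_covariates(60, seed=6)
        cov["x6"] = cov["x5"]  # exact collinearity
        with pytest.raises(ValueError, match="rank"):
            cs.fit_plaqr(cov.assign(cost=np.arange(60) + 1.0))


class TestRandomForest:
    def test_predictions_within_training_range(self, gamma_data):
        res = cs.fit_rf(gamma_data, spec=ModelSpec("rf", rf_ntree=40, rf_mtry=4, seed=1))
        new = cs.generate_covariates(200, seed=99)
        pred = res.predict(new)
        assert pred.min() >= gamma_data.cost.min()
        assert pred.max() <= gamma_data.cost.max()

    def test_step_function_recovery(self):
        rng = np.random.default_rng(800)
        cov = cs.generate_covariates(1500, seed=8)
        cost = 100.0 + 50.0 * cov.x3.to_numpy() + rng.normal(0, 1, 1500)
        res = cs.fit_rf(cov.assign(cost=cost), spec=ModelSpec("rf", rf_ntree=100, rf_mtry=10, seed=2))
        pred = res.predict(cov)
        assert pred[cov.x3 == 0].mean() == pytest.approx(100.0, abs=2.0)
        assert pred[cov.x3 == 1].mean() == pytest.approx(150.0, abs=2.0)

    def test_seeded_determinism_and_specification_invariance(self, gamma_data):
        spec = ModelSpec("rf", "correct", rf_ntree=30, rf_mtry=5, seed=7)
        a = cs.fit_rf(gamma_data, spec=spec).predict(gamma_data.covariates)
        b = cs.fit_rf(gamma_data, spec=spec).predict(gamma_data.covariates)
        assert np.array_equal(a, b)
        # the specification flag only affects the regression models
        alt = ModelSpec("rf", "main_effects", rf_ntree=30, rf_mtry=5, seed=7)
        c = cs.fit_rf(gamma_data, spec=alt).predict(gamma_data.covariates)
        assert np.array_equal(a, c)

    def test_mtry_tuned_by_oob_error(self, gamma_data):
        grid = (2, 5, 8)
        res = cs.fit_rf(
            gamma_data,
            spec=ModelSpec("rf", rf_ntree=30, rf_mtry_grid=grid, rf_tune_ntree=30, seed=3),
        )
        oob = res.diagnostics["oob_mse_by_mtry"]
        assert set(oob) == set(grid)
        assert res.diagnostics["mtry"] == min(grid, key=lambda m: (oob[m], m))

    def test_oob_rmse_tracks_holdout_rmse(self):
        d = cs.simulate_dataset(1000, "gamma", seed=6)
        train, test = d.subset(range(700)), d.subset(range(700, 1000))
        res = cs.fit_rf(train, spec=ModelSpec("rf", rf_ntree=200, rf_mtry=7, seed=1))
        holdout = cs.rmse(test.cost, res.predict(test.covariates))
        assert 0.6 < res.diagnostics["oob_rmse"] / holdout < 1.5

    def test_requires_two_rows(self):
        cov = cs.generate_covariates(1, seed=0)
        with pytest.raises(ValueError):
            cs.fit_rf(cov.assign(cost=1.0))


class TestPredictContract:
    def test_row_permutation_equivariance(self, gamma_data):
        res = cs.fit_rf(gamma_data, spec=ModelSpec("rf", rf_ntree=25, rf_mtry=4, seed=4))
        cov = gamma_data.covariates
        perm = np.random.default_rng(1).permutation(gamma_data.n)
        assert np.array_equal(res.predict(cov)[perm], res.predict(cov.iloc[perm]))

    def test_schema_mismatch_raises(self, gamma_data):
        res = cs.fit_gamma_glm(gamma_data)
        with pytest.raises(KeyError):
            res.predict(gamma_data.covariates.drop(columns=["x8"]))
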