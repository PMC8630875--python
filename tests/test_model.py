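import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import geoadditive as ga
from geoadditive.model import (
    GeoAdditiveLogistic,
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    assemble_design,
    diagnostics,
    effect_code,
    fit_mcmc,
)

WEALTH = ["Poorest", "Poor", "Middle", "Rich", "Richest"]


class TestEffectCode:
    def test_non_reference_level_is_indicator(self):
        np.testing.assert_allclose(
            effect_code(WEALTH, "Poorest", "Poor"), [1, 0, 0, 0])

    def test_reference_level_is_all_minus_one(self):
        np.testing.assert_allclose(
            effect_code(WEALTH, "Poorest", "Poorest"), [-1, -1, -1, -1])

    def test_balanced_two_level_column_sums_to_zero(self):
        rows = [effect_code(["No", "Yes"], "No", v)
                for v in ["Yes"] * 50 + ["No"] * 50]
        assert np.sum(rows) == 0

    def test_unknown_level_named_in_error(self):
        with pytest.raises(ValueError, match="Unknown|unknown"):
            effect_code(WEALTH, "Poorest", "VeryRich")


class TestMcmcConfig:
    def test_retained_draws_formula(self):
        cfg = McmcConfig(n_iter=40_000, n_burnin=10_000, thin=1)
        assert cfg.n_retained == 30_000

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, n_burnin=10, thin=0)


class TestAssembleDesign:
    def _binary_frame(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            c: rng.choice(["No", "Yes"], n) for c in ["a", "b", "c"]
        })

    def test_m0_design_is_intercept_plus_coded_columns(self):
        df = self._binary_frame()
        spec = ModelSpec(form="M0",
                         fixed={c: ["No", "Yes"] for c in ["a", "b", "c"]})
        blocks = assemble_design(df, spec)
        assert blocks.fixed.X.shape == (200, 4)
        assert blocks.smooths == [] and blocks.spatial is None

    def test_m3_penalized_parameter_count(self, small_dataset):
        ds = small_dataset
        spec = ModelSpec(
            form="M3",
            fixed={"sex": ["Female", "Male"]},
            smooths={c: {} for c in ["child_age_months", "mother_age_years",
                                     "breastfeeding_months"]},
            spatial="tensor", spatial_segments=8,
        )
        blocks = assemble_design(ds.data, spec, geography=ds.geography)
        n_pen = sum(sb.X.shape[1] for sb in blocks.smooths)
        n_pen += blocks.spatial.Z.shape[1]
        assert n_pen == 3 * 23 + 121

    def test_penalized_blocks_are_centered(self, small_dataset):
        ds = small_dataset
        spec = ModelSpec(form="M1", fixed={"sex": ["Female", "Male"]},
                         smooths={"child_age_months": {}})
        blocks = assemble_design(ds.data, spec)
        assert np.abs(blocks.smooths[0].X.mean(axis=0)).max() < 1e-10

    def test_spatial_block_centered_with_child_weights(self, small_dataset):
        ds = small_dataset
        spec = ModelSpec(form="M2", fixed={"sex": ["Female", "Male"]},
                         spatial="tensor", spatial_segments=4)
        blocks = assemble_design(ds.data, spec, geography=ds.geography)
        child_rows = blocks.spatial.Z[blocks.spatial.region_index]
        assert np.abs(child_rows.mean(axis=0)).max() < 1e-10

    def test_missing_values_dropped_complete_case(self, caplog):
        df = self._binary_frame(50)
        df.loc[3, "a"] = np.nan
        df.loc[7, "b"] = np.nan
        spec = ModelSpec(form="M0",
                         fixed={c: ["No", "Yes"] for c in ["a", "b", "c"]})
        with caplog.at_level("INFO", logger="geoadditive.model"):
            blocks = assemble_design(df, spec)
        assert blocks.n_obs == 48 and blocks.n_dropped == 2
        assert any("2 rows" in r.message for r in caplog.records)

    def test_form_consistency_enforced(self):
        with pytest.raises(ValueError, match="disagree"):
            ModelSpec(form="M0", fixed={}, smooths={"x": {}})


class TestSamplerCorrectness:
    def test_intercept_only_recovers_logit_p(self):
        rng = np.random.default_rng(31)
        y = (rng.uniform(size=5000) < 0.3).astype(float)
        blocks = assemble_design(pd.DataFrame(index=range(5000)),
                                 ModelSpec(form="M0", fixed={}))
        draws = fit_mcmc(blocks, y, McmcConfig(2500, 500, seed=1))
        m, s = draws.beta.mean(), draws.beta.std()
        assert abs(m - logit(y.mean())) < 3 * s

    def test_one_covariate_matches_irls_oracle(self):
        rng = np.random.default_rng(37)
        n = 5000
        x = rng.choice([0.0, 1.0], n)
        eta = -0.4 + 0.7 * x
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"g": np.where(x > 0, "Yes", "No")})
        blocks = assemble_design(df, ModelSpec(form="M0",
                                               fixed={"g": ["No", "Yes"]}))
        draws = fit_mcmc(blocks, y, McmcConfig(2500, 500, seed=2))
        import statsmodels.api as sm
        X = np.column_stack([np.ones(n), np.where(x > 0, 1.0, -1.0)])
        mle = sm.Logit(y, X).fit(disp=0).params
        for j in range(2):
            assert abs(draws.beta[:, j].mean() - mle[j]) \
                < 3 * draws.beta[:, j].std()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(41)
        y = (rng.uniform(size=300) < 0.4).astype(float)
        blocks = assemble_design(pd.DataFrame(index=range(300)),
                                 ModelSpec(form="M0", fixed={}))
        a = fit_mcmc(blocks, y, McmcConfig(200, 50, seed=5))
        b = fit_mcmc(blocks, y, McmcConfig(200, 50, seed=5))
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_non_binary_outcome_rejected(self):
        blocks = assemble_design(pd.DataFrame(index=range(10)),
                                 ModelSpec(form="M0", fixed={}))
        with pytest.raises(ValueError, match="binary"):
            fit_mcmc(blocks, np.full(10, 0.5), McmcConfig(100, 10, seed=0))

    def test_prior_only_draws_follow_random_walk_scale(self, small_dataset):
        """With the likelihood switched off and tau^2 fixed, the order-d
        differences of smooth coefficients are N(0, tau^2)."""
        ds = small_dataset
        spec = ModelSpec(form="M1", fixed={},
                         smooths={"child_age_months": {"rw_order": 2}})
        blocks = assemble_design(ds.data, spec)
        tau2 = 0.5
        draws = fit_mcmc(blocks, ds.data.anaemic.to_numpy(dtype=float),
                         McmcConfig(3000, 500, seed=3),
                         likelihood_weight=0.0, fix_tau2=tau2)
        theta = draws.smooth_coefs["child_age_months"]
        d2 = np.diff(theta, n=2, axis=1)
        assert d2.std() == pytest.approx(np.sqrt(tau2), rel=0.1)


def _pseudo_draws(beta, names):
    S = beta.shape[0]
    return PosteriorDraws(
        beta=beta, beta_names=names, smooth_coefs={}, spatial_coefs=None,
        tau2={}, deviance=np.full(S, 100.0), deviance_at_mean=100.0,
        eta_mean=np.zeros(1), n_obs=1,
        config=McmcConfig(n_iter=S + 1, n_burnin=1, seed=0),
    )


class TestDiagnostics:
    def test_white_noise_has_negligible_lag_one_acf(self):
        rng = np.random.default_rng(43)
        d = _pseudo_draws(rng.standard_normal((10_000, 1)), ["b"])
        rep = diagnostics(d)
        assert abs(rep.loc["b", "acf1"]) < 0.05

    def test_ar1_lag_one_acf_near_rho(self):
        rng = np.random.default_rng(47)
        n, rho = 10_000, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        rep = diagnostics(_pseudo_draws(x[:, None], ["b"]))
        assert rep.loc["b", "acf1"] == pytest.approx(rho, abs=0.05)
        assert rep.loc["b", "ess"] < n / 10

    def test_constant_chain_flagged_degenerate(self):
        rep = diagnostics(_pseudo_draws(np.ones((500, 1)), ["b"]))
        assert bool(rep.loc["b", "degenerate"])
        assert np.isnan(rep.loc["b", "ess"])

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            diagnostics(_pseudo_draws(np.zeros((50, 1)), ["b"]))


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        m = GeoAdditiveLogistic(form="M1", n_iter=500)
        params = m.get_params()
        assert params["form"] == "M1"
        m2 = GeoAdditiveLogistic(**params)
        assert m2.get_params() == params

    def test_fitted_attributes_and_prediction(self, small_m3_fit,
                                              small_dataset):
        m = small_m3_fit
        assert m.draws_.n_draws == 1000
        assert m.dic_.dic > 0
        proba = m.predict_proba(small_dataset.data.head(50))
        assert proba.shape == (50, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        # predictions should discriminate: mean p near observed prevalence
        assert 0.4 < proba[:, 1].mean() < 0.75

    def test_unfitted_estimator_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            GeoAdditiveLogistic().fixed_effect_table()

    def test_trace_frame_exports_scalar_chains(self, small_m3_fit):
        tr = small_m3_fit.draws_.trace_frame()
        assert len(tr) == small_m3_fit.draws_.n_draws
        assert "deviance" in tr.columns
        assert "tau2[spatial]" in tr.columns
        assert "mother_anaemic[Yes]" in tr.columns

    def test_draws_save_load_roundtrip(self, tmp_path, small_m3_fit):
        d = small_m3_fit.draws_
        d.save(tmp_path / "draws")
        d2 = PosteriorDraws.load(tmp_path / "draws")
        np.testing.assert_array_equal(d.beta, d2.beta)
        np.testing.assert_array_equal(
            d.smooth_coefs["child_age_months"],
            d2.smooth_coefs["child_age_months"])
        np.testing.assert_array_equal(d.spatial_coefs, d2.spatial_coefs)
        assert d2.config == d.config

    def test_mrf_mode_fits(self, small_dataset):
        ds = small_dataset
        m = GeoAdditiveLogistic(form="M2", spatial="mrf", n_iter=300,
                                n_burnin=100, random_state=1)
        m.fit(ds.data, "anaemic", geography=ds.geography)
        assert m.draws_.spatial_coefs.shape == (200, 36)
        assert m.blocks_.spatial.basis.mode == "mrf"
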