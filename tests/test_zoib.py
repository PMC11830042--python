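"""ZOIB density, proportion conversion, HMC machinery and the multilevel fit."""
import numpy as np
import pandas as pd
import pytest

from implfx.errors import ConvergenceError, ParameterError
from implfx.simulate import SurveySimParams, simulate_survey
from implfx.zoib import (
    MultilevelSpec,
    PredictorRanking,
    ZOIBParams,
    ZOIBPosterior,
    _ZOIBModel,
    fit_zoib_multilevel,
    rank_predictors,
    to_proportion,
    zoib_logdensity,
)

FAST = dict(chains=2, warmup=150, draws=150, max_leapfrog=24,
            rhat_threshold=5.0, min_ess=1.0)  # machinery-level settings


class TestToProportion:
    @pytest.mark.parametrize("score, mx, expected", [
        (100.0, 100.0, 1.0), (50.0, 100.0, 0.5), (0.0, 100.0, 0.0), (3.0, 4.0, 0.75),
    ])
    def test_examples(self, score, mx, expected):
        assert to_proportion(score, mx) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError, match="outside"):
            to_proportion(101.0, 100.0)
        with pytest.raises(ParameterError, match="max_score"):
            to_proportion(1.0, 0.0)


class TestDensity:
    def test_point_mass_products(self):
        p = ZOIBParams(alpha=0.2, gamma=0.5, mu=0.4, phi=3.0)
        assert zoib_logdensity(1.0, p) == pytest.approx(np.log(0.1))
        assert zoib_logdensity(0.0, p) == pytest.approx(np.log(0.1))

    def test_uniform_interior_identity(self):
        p = ZOIBParams(alpha=0.0, gamma=0.5, mu=0.5, phi=2.0)  # Beta(1, 1)
        assert zoib_logdensity(0.5, p) == pytest.approx(0.0, abs=1e-12)

    def test_normalizes_for_random_parameters(self, rng):
        from scipy.integrate import quad

        for _ in range(20):
            p = ZOIBParams(alpha=rng.uniform(0, 1), gamma=rng.uniform(0, 1),
                           mu=rng.uniform(0.05, 0.95), phi=rng.uniform(0.5, 50))
            interior, _ = quad(lambda y: np.exp(zoib_logdensity(y, p)), 0, 1,
                               limit=200)
            total = p.alpha + interior
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ZOIBParams(alpha=1.2, gamma=0.5, mu=0.5, phi=1.0)
        with pytest.raises(ParameterError):
            ZOIBParams(alpha=0.5, gamma=0.5, mu=0.0, phi=1.0)
        with pytest.raises(ParameterError):
            zoib_logdensity(1.5, ZOIBParams(alpha=0.1, gamma=0.5, mu=0.5, phi=1.0))


class TestGradientAndSampler:
    def test_analytic_gradient_matches_finite_differences(self, small_survey):
        model = _ZOIBModel(small_survey, MultilevelSpec(**FAST))
        rng = np.random.default_rng(1)
        x = model.initial_point(rng) + 0.05 * rng.normal(size=model.dim)
        lp, g = model.logp_grad(x)
        eps = 1e-6
        idx = list(range(6)) + [model.dim // 2, model.dim - 1]
        for i in idx:
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (model.logp_grad(xp)[0] - model.logp_grad(xm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_hmc_recovers_correlated_gaussian(self):
        from implfx._hmc import sample_hmc

        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)

        def logp_grad(x):
            return -0.5 * float(x @ prec @ x), -prec @ x

        rng = np.random.default_rng(0)
        res = sample_hmc(logp_grad, np.zeros(2), 300, 1500, rng, max_leapfrog=16,
                         dense_idx=np.array([0, 1]))
        est = np.cov(res.draws.T)
        assert np.allclose(est, cov, atol=0.15)
        assert res.divergences == 0


class TestMultilevelFit:
    def test_degenerate_hierarchy_drops_levels(self):
        table = simulate_survey(SurveySimParams(
            n_domains=1, n_components_per_domain=1, n_items_per_component=4,
            n_participants=30, seed=2,
        ))
        post = fit_zoib_multilevel(table, MultilevelSpec(**FAST, seed=0))
        assert set(post.dropped_levels) == {"domain", "component"}
        assert "sd_item_slope" in post.draws
        assert "sd_domain_slope" not in post.draws

    def test_interior_only_fit_matches_beta_regression_oracle(self):
        # no hierarchy variance, no inflation: the fixed effects must agree
        # with a frequentist beta-regression fit on the same data
        from statsmodels.othermod.betareg import BetaModel

        p = SurveySimParams(
            n_domains=2, n_components_per_domain=2, n_items_per_component=2,
            n_participants=150, base_intercept=0.3, base_slope=0.8,
            sd_domain_int=0, sd_domain_slope=0, sd_component_int=0,
            sd_component_slope=0, sd_item_int=0, sd_item_slope=0,
            sd_participant=0, inflate_alpha=0.0, precision_phi=20.0, seed=6,
        )
        table = simulate_survey(p)
        X = np.column_stack([np.ones(len(table.data)), table.data["success"]])
        mle = BetaModel(table.data["rating"], X).fit(disp=False)
        # hyper-SDs sit on the zero boundary here and their chains wander in
        # the flat log-SD tail; the quantities under test (fixed effects) mix
        # well, so the convergence gate is held open deliberately
        spec = MultilevelSpec(chains=2, warmup=300, draws=300, max_leapfrog=48,
                              rhat_threshold=5.0, min_ess=1.0, seed=3)
        post = fit_zoib_multilevel(table, spec)
        b0 = float(np.median(post.stacked("b0")))
        b1 = float(np.median(post.stacked("b1")))
        assert b0 == pytest.approx(mle.params[0], abs=0.1)
        assert b1 == pytest.approx(mle.params[1], abs=0.15)

    def test_nonconvergence_raises_with_offenders(self, small_survey):
        spec = MultilevelSpec(chains=2, warmup=60, draws=60, max_leapfrog=4,
                              rhat_threshold=1.0000001, min_ess=1e6, seed=0)
        with pytest.raises(ConvergenceError) as err:
            fit_zoib_multilevel(small_survey, spec)
        assert err.value.offenders  # names attached

    def test_rating_range_validated(self, small_survey):
        bad = small_survey.data.copy()
        bad.loc[0, "rating"] = 1.2
        from implfx.datasets import SurveyTable
        from implfx.errors import DataError

        with pytest.raises(DataError):
            _ZOIBModel(SurveyTable(bad), MultilevelSpec(**FAST))


def _fake_posterior(sd_draws: dict, slope_draws: dict, groups: dict) -> ZOIBPosterior:
    draws = {f"sd_{k}_slope": v for k, v in sd_draws.items()}
    draws.update({f"{k}_slope": v for k, v in slope_draws.items()})
    draws["b1"] = np.zeros((2, 50))
    return ZOIBPosterior(draws=draws, groups=groups, diagnostics=pd.DataFrame(),
                         divergences=0, dropped_levels=[], spec=MultilevelSpec(**FAST))


class TestRanking:
    def test_dominant_level_ranked_first_and_deterministic(self):
        rng = np.random.default_rng(0)
        post = _fake_posterior(
            {"domain": np.full((2, 50), 0.1) + 0.01 * rng.random((2, 50)),
             "component": np.full((2, 50), 0.5),
             "item": np.full((2, 50), 0.05)},
            {"domain": np.zeros((2, 50, 2)), "component": np.zeros((2, 50, 2)),
             "item": np.zeros((2, 50, 2))},
            {"domain": ["D1", "D2"], "component": ["C1", "C2"], "item": ["I1", "I2"]},
        )
        r1 = rank_predictors(post)
        r2 = rank_predictors(post)
        assert isinstance(r1, PredictorRanking)
        assert r1.best_level == "component"
        assert list(r1.levels["level"]) == ["component", "domain", "item"]
        pd.testing.assert_frame_equal(r1.levels, r2.levels)

    def test_identical_groups_tie_break_lexicographic(self):
        eff = np.zeros((2, 50, 2))
        post = _fake_posterior(
            {"domain": np.full((2, 50), 0.2)},
            {"domain": eff},
            {"domain": ["Zeta", "Alpha"]},
        )
        r = rank_predictors(post)
        assert list(r.group_slopes["domain"]["group"]) == ["Alpha", "Zeta"]
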