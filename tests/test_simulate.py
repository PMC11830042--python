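"""Generator behavior: planted structure, seed determinism, parameter checks."""
import numpy as np
import pytest

from implfx.errors import ConfigurationError, ParameterError, StructuralError
from implfx.simulate import (
    ITSSimParams,
    QCASimParams,
    SurveySimParams,
    simulate_its,
    simulate_panel,
    simulate_qca,
    simulate_survey,
)


class TestSimulateITS:
    def test_noiseless_step(self, step_series):
        assert np.allclose(step_series[:12], 10.0)
        assert np.allclose(step_series[12:], 20.0)

    def test_innovation_sd_matches_long_run(self):
        p = ITSSimParams(n_pre=10000, n_post=3, pre_sd=1.0, pre_ac=0.0, seed=4)
        y = simulate_its(p)[:10000]
        assert np.std(y) == pytest.approx(1.0, rel=0.02)

    def test_lag1_autocorrelation_recovered(self):
        p = ITSSimParams(n_pre=20000, n_post=3, pre_sd=1.0, pre_ac=0.5, seed=9)
        e = simulate_its(p)[:20000]  # flat mean: series is the AR process
        r = np.corrcoef(e[1:], e[:-1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_seed_determinism_bitwise(self):
        p = ITSSimParams(n_pre=24, n_post=24, pre_sd=1.0, post_sd=2.0,
                         pre_ac=0.4, post_ac=-0.2, seed=11)
        assert np.array_equal(simulate_its(p), simulate_its(p))

    @pytest.mark.parametrize("shift", [0, 2, 5])
    def test_regime_placement_shifts_with_changepoint(self, shift):
        p = ITSSimParams(n_pre=12 + shift, n_post=12, pre_intercept=0.0,
                         post_intercept=1.0, pre_sd=0.0, post_sd=0.0, seed=0)
        y = simulate_its(p)
        first_one = int(np.argmax(y == 1.0)) + 1
        assert first_one == 13 + shift == p.true_changepoint

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(n_pre=2, n_post=12), "n_pre"),
            (dict(n_pre=12, n_post=12, pre_sd=-1.0), "SD"),
            (dict(n_pre=12, n_post=12, pre_ac=1.0), "ac"),
            (dict(n_pre=12, n_post=12, true_changepoint=10), "true_changepoint"),
            (dict(n_pre=12, n_post=12, nominal_intervention=20), "nominal"),
        ],
    )
    def test_invalid_params_named(self, kwargs, match):
        with pytest.raises(ParameterError, match=match):
            ITSSimParams(**kwargs)


class TestSimulatePanel:
    def _unit(self, seed=0, **kw):
        base = dict(n_pre=24, n_post=24, pre_sd=1.0, post_sd=1.0, seed=seed)
        base.update(kw)
        return ITSSimParams(**base)

    def test_shape_10x7x48(self):
        panel = simulate_panel([self._unit(seed=i) for i in range(10)], n_metrics=7)
        assert len(panel.data) == 10 * 7 * 48
        assert len(panel.units) == 10 and len(panel.metrics) == 7

    def test_variance_halving_everywhere(self):
        params = [self._unit(seed=i, n_pre=400, n_post=400, post_sd=0.5)
                  for i in range(4)]
        panel = simulate_panel(params, n_metrics=1)
        for unit in panel.units:
            y = panel.series(unit, panel.metrics[0])
            assert np.var(y[400:]) < np.var(y[:400])

    def test_degenerate_panel_equals_single_series(self):
        p = self._unit(seed=42)
        panel = simulate_panel([p], n_metrics=1)
        assert np.array_equal(panel.series(panel.units[0], panel.metrics[0]),
                              simulate_its(p))

    def test_mismatched_ranges_rejected(self):
        with pytest.raises(StructuralError, match="month range"):
            simulate_panel([self._unit(), self._unit(n_post=30)])


class TestSimulateSurvey:
    def test_full_inflation_gives_all_ones(self):
        t = simulate_survey(SurveySimParams(n_participants=20, inflate_alpha=1.0,
                                            inflate_gamma=1.0, seed=0))
        assert (t.data["rating"] == 1.0).all()

    def test_symmetric_interior_mean_half(self):
        p = SurveySimParams(
            n_participants=400, inflate_alpha=0.0, base_intercept=0.0, base_slope=0.0,
            sd_domain_int=0, sd_domain_slope=0, sd_component_int=0,
            sd_component_slope=0, sd_item_int=0, sd_item_slope=0, sd_participant=0,
            seed=3,
        )
        t = simulate_survey(p)
        assert t.data["rating"].mean() == pytest.approx(0.5, abs=0.01)

    def test_row_count_is_product_of_counts(self):
        t = simulate_survey(SurveySimParams(n_domains=5, n_components_per_domain=3,
                                            n_items_per_component=2,
                                            n_participants=100, seed=1))
        assert len(t.data) == 5 * 3 * 2 * 100

    def test_support_and_endpoint_mass(self):
        p = SurveySimParams(n_participants=300, inflate_alpha=0.2, seed=5)
        t = simulate_survey(p)
        r = t.data["rating"].to_numpy()
        assert ((0 <= r) & (r <= 1)).all()
        frac = np.mean((r == 0) | (r == 1))
        n = len(r)  # binomial 99.9% interval around 0.2
        half = 3.3 * np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < half

    def test_truth_sidecar_lists_hyper_sds(self, small_survey):
        assert set(small_survey.truth["hyper_sd"]) == {
            "domain_int", "domain_slope", "component_int", "component_slope",
            "item_int", "item_slope", "participant_int",
        }


class TestSimulateQCA:
    def test_crisp_planted_rule_exact(self):
        d = simulate_qca(QCASimParams(n_cases=100, planted_solution="A",
                                      condition_names=("A", "B"), seed=2))
        a = d.memberships["A"].to_numpy()
        y = d.outcome.to_numpy()
        assert np.array_equal(y[a == 1], np.ones((a == 1).sum()))

    def test_forced_necessity_is_perfect_subset(self):
        d = simulate_qca(QCASimParams(n_cases=100, planted_solution="A",
                                      necessity_condition="P",
                                      condition_names=("A", "P"), seed=3))
        p = d.memberships["P"].to_numpy()
        y = d.outcome.to_numpy()
        assert (np.minimum(p, y) == y).all()

    def test_noise_rate_shows_in_consistency(self):
        from implfx.qca import sufficiency

        d = simulate_qca(QCASimParams(n_cases=200, planted_solution="A",
                                      noise_rate=0.1, seed=4))
        cons = sufficiency(d.memberships["A"], d.outcome).consistency
        half = 3.3 * np.sqrt(0.1 * 0.9 / 100)  # ~half the cases have A=1
        assert abs(cons - 0.9) < half

    def test_contradictory_necessity_rejected(self):
        with pytest.raises(ConfigurationError, match="negated"):
            simulate_qca(QCASimParams(planted_solution="A*~P",
                                      condition_names=("A", "P"),
                                      necessity_condition="P"))

    def test_fuzzy_memberships_in_unit_interval(self):
        d = simulate_qca(QCASimParams(n_cases=50, crisp=False, seed=8))
        m = d.memberships.to_numpy()
        assert ((0 <= m) & (m <= 1)).all() and not d.crisp
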