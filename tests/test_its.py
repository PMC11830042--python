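"""Robust-ITS: exact recovery, oracle agreement, nested-likelihood laws,
estimator consistency and panel reporting."""
import numpy as np
import pytest

from implfx.errors import DataError, DegenerateFitError, StructuralError
from implfx.its import (
    ITSModelConfig,
    analyze_panel,
    fit_robust_its,
    holm,
    _profile_constrained,
    _segment_concentrated,
)
from implfx.simulate import ITSSimParams, simulate_its, simulate_panel, unit_gain_scenario


def _sim(seed, n_pre=24, n_post=24, **kw):
    base = dict(pre_intercept=50.0, post_intercept=50.0, pre_sd=1.0, post_sd=1.0,
                pre_ac=0.3, post_ac=0.3)
    base.update(kw)
    return simulate_its(ITSSimParams(n_pre=n_pre, n_post=n_post, seed=seed, **base))


def _oracle_changepoint(y, cands):
    """Independent exhaustive refit: per candidate, golden-section search of
    the concentrated AR(1) likelihood on each segment over a fine rho grid."""
    def seg_ll(t, yy):
        grid = np.linspace(-0.99, 0.99, 397)
        lls = np.array([_oracle_seg(t, yy, r) for r in grid])
        return lls.max()

    def _oracle_seg(t, yy, rho):
        m = len(yy)
        X = np.column_stack([np.ones(m), t])
        f = np.sqrt(1 - rho * rho)
        Xs = np.vstack([X[0] * f, X[1:] - rho * X[:-1]])
        ys = np.concatenate([[yy[0] * f], yy[1:] - rho * yy[:-1]])
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        q = ys - Xs @ b
        s2 = max(q @ q / m, 1e-300)
        return -0.5 * m * (np.log(2 * np.pi) + 1) - 0.5 * m * np.log(s2) \
            + 0.5 * np.log(1 - rho * rho)

    n = len(y)
    best, best_ll = None, -np.inf
    for tau in cands:
        ll = seg_ll(np.arange(1.0, tau), y[: tau - 1]) + seg_ll(
            np.arange(1.0, n - tau + 2), y[tau - 1 :]
        )
        if ll > best_ll + 1e-9:
            best, best_ll = tau, ll
    return best


class TestFit:
    def test_noiseless_step_recovered_exactly(self, step_series):
        cfg = ITSModelConfig(inference="asymptotic_lrt")
        fit = fit_robust_its(step_series, cfg, nominal_intervention=13)
        assert fit.changepoint_hat == 13
        assert fit.mean_change_estimate == pytest.approx(10.0, abs=1e-9)
        assert fit.degenerate and np.isnan(fit.variance_ratio)
        assert fit.tests["mean"].p_value == 0.0
        assert np.isnan(fit.tests["variance"].p_value)

    def test_changepoint_agrees_with_brute_force_oracle(self):
        cfg = ITSModelConfig(inference="asymptotic_lrt")
        master = np.random.default_rng(77)
        for _ in range(25):
            y = _sim(int(master.integers(2**31)), post_intercept=50.8, post_sd=0.8)
            fit = fit_robust_its(y, cfg, nominal_intervention=25, with_tests=False)
            assert fit.changepoint_hat == _oracle_changepoint(y, fit.candidates)

    def test_profile_argmax_and_loglik_invariants(self):
        y = _sim(5, post_intercept=52.0)
        fit = fit_robust_its(y, ITSModelConfig(inference="asymptotic_lrt"),
                             nominal_intervention=25)
        assert fit.loglik == pytest.approx(fit.profile.max())
        assert fit.changepoint_hat == fit.profile.idxmax()
        assert fit.changepoint_hat in fit.candidates
        assert fit.sd_hat_pre >= 0 and abs(fit.ac_hat_pre) < 1

    def test_ols_limit_at_zero_autocorrelation(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 31.0)
        y = 2.0 + 0.3 * t + rng.normal(0, 1, 30)
        _, beta, s2, _ = _segment_concentrated(t, y, 0.0)
        X = np.column_stack([np.ones(30), t])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta, beta_ols, atol=1e-8)
        resid = y - X @ beta_ols
        assert s2 == pytest.approx(resid @ resid / 30, abs=1e-10)

    def test_gapped_and_constant_series_rejected(self):
        cfg = ITSModelConfig()
        with pytest.raises(DataError, match="missing"):
            fit_robust_its(np.concatenate([np.ones(10), [np.nan], np.ones(10)]), cfg)
        with pytest.raises(DataError, match="contiguous"):
            fit_robust_its(np.arange(20.0), cfg,
                           months=np.concatenate([np.arange(1, 11), np.arange(12, 22)]))
        with pytest.raises(DegenerateFitError, match="flat"):
            fit_robust_its(np.full(20, 7.0), cfg)


class TestInference:
    def test_full_loglik_dominates_every_constrained_fit(self):
        master = np.random.default_rng(8)
        for _ in range(5):
            y = _sim(int(master.integers(2**31)))
            fit = fit_robust_its(y, ITSModelConfig(inference="asymptotic_lrt"),
                                 nominal_intervention=25, with_tests=False)
            for kind in ("mean", "variance", "autocorrelation"):
                ll_c, _ = _profile_constrained(y, fit.candidates, kind)
                assert fit.loglik >= ll_c - 1e-7

    def test_bootstrap_p_values_reproducible(self):
        y = _sim(21, post_sd=0.6)
        cfg = ITSModelConfig(n_boot=49, seed=5)
        f1 = fit_robust_its(y, cfg, nominal_intervention=25)
        f2 = fit_robust_its(y, cfg, nominal_intervention=25)
        assert all(f1.tests[k].p_value == f2.tests[k].p_value for k in f1.tests)

    def test_changepoint_rmse_shrinks_with_effect_size(self):
        cfg = ITSModelConfig(inference="asymptotic_lrt")
        rmses = []
        for step in (0.5, 1.5, 4.0):
            master = np.random.default_rng(int(step * 1000))
            errs = []
            for _ in range(30):
                y = _sim(int(master.integers(2**31)), post_intercept=50.0 + step)
                fit = fit_robust_its(y, cfg, nominal_intervention=25, with_tests=False)
                errs.append((fit.changepoint_hat - 25) ** 2)
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_variance_ratio_ci_covers_truth(self):
        # sigma doubled post (variance ratio 4), strong mean shift, n=120
        hits = 0
        master = np.random.default_rng(60)
        for _ in range(60):
            y = _sim(int(master.integers(2**31)), n_pre=60, n_post=60,
                     post_intercept=55.0, post_sd=2.0)
            fit = fit_robust_its(y, ITSModelConfig(inference="asymptotic_lrt"),
                                 nominal_intervention=61, with_tests=False)
            est, (lo, hi) = __import__("implfx.its", fromlist=["_point_estimates"])\
                ._point_estimates(fit)["variance"]
            hits += int(lo <= 4.0 <= hi)
        # binomial 99.8% band around 0.95 with 60 draws
        assert 48 <= hits <= 60

    def test_holm_adjustment_properties(self):
        p = np.array([0.001, 0.02, 0.04, 0.5])
        adj = holm(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.004)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPanel:
    def test_empty_panel_rejected(self):
        import pandas as pd

        from implfx.datasets import TimeSeriesPanel

        with pytest.raises(StructuralError):
            TimeSeriesPanel(pd.DataFrame(columns=["unit", "metric", "month", "value"]))

    def test_failing_unit_reported_not_dropped(self):
        params = [ITSSimParams(n_pre=24, n_post=24, pre_sd=1.0, post_sd=1.0, seed=i)
                  for i in range(2)]
        panel = simulate_panel(params, n_metrics=1)
        # make one unit constant: it must fail and be listed
        mask = panel.data["unit"] == panel.units[0]
        panel.data.loc[mask, "value"] = 5.0
        cfg = ITSModelConfig(n_boot=19, seed=0)
        report = analyze_panel(panel, cfg)
        assert list(report.failures["unit"]) == [panel.units[0]]
        assert set(report.per_unit["unit"]) == {panel.units[1]}

    def test_planted_unit_gains_flagged_at_unit_level(self):
        panel = unit_gain_scenario(seed=0)
        cfg = ITSModelConfig(n_boot=499, seed=1)
        report = analyze_panel(panel, cfg)
        gain_units = set(panel.truth["gain_units"])
        per_unit = report.per_unit.set_index("unit")
        # every planted gain shows raw significance ...
        assert (per_unit.loc[sorted(gain_units), "mean_p"] <= 0.05).all()
        # ... most survive the Holm correction across the 10 units ...
        flagged = set(per_unit.index[per_unit["mean_flag"]])
        assert len(flagged & gain_units) >= 2
        # ... and familywise false flags stay controlled
        assert len(flagged - gain_units) <= 1
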