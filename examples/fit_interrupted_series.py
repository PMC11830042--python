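"""Fit the robust interrupted time series model to one monthly outcome series.

Simulates four years of a unit-level satisfaction score whose regime
switches three months after the intervention month (a lag): the level rises
by 2 points, the innovation SD halves, the autocorrelation rises. The fit
estimates the change point by profile likelihood and tests all three kinds
of change with the parametric bootstrap.
"""
from implfx import ITSModelConfig, ITSSimParams, fit_robust_its, simulate_its

params = ITSSimParams(
    n_pre=24, n_post=24,
    pre_intercept=80.0, post_intercept=83.0,   # level gain of 3 points
    pre_sd=1.0, post_sd=0.5,                   # variance drops to a quarter
    pre_ac=0.3, post_ac=0.5,                   # dependence strengthens
    nominal_intervention=22,                   # regime switches at month 25: lag 3
    seed=42,
)
y = simulate_its(params)
fit = fit_robust_its(y, ITSModelConfig(n_boot=199, seed=1), nominal_intervention=22)

print(f"estimated change point: month {fit.changepoint_hat} "
      f"(truth {params.true_changepoint}, intervention at {params.nominal_intervention})")
print(f"innovation SD pre/post: {fit.sd_hat_pre:.3f} / {fit.sd_hat_post:.3f}")
print(f"autocorrelation pre/post: {fit.ac_hat_pre:.3f} / {fit.ac_hat_post:.3f}")
for name, tr in fit.tests.items():
    print(f"{name:16s} estimate={tr.estimate:7.3f}  "
          f"ci=({tr.ci[0]:.3f}, {tr.ci[1]:.3f})  p={tr.p_value:.3f}")
print("\nThe mean estimate is the level change at the change point; the")
print("variance estimate is the post/pre innovation-variance ratio (a value")
print("below 1 means outcomes became more consistent); p-values come from a")
print("parametric bootstrap that re-estimates the change point per replicate.")
print("Note the honest mean-change p-value: with only 48 months and a null")
print("model whose free autocorrelation can absorb slow drifts, a 3-point")
print("level shift is genuinely hard to distinguish from dependence.")
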