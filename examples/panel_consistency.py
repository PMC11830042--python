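"""Consistency-in-outcome across a panel of clinical units.

Builds a 10-unit panel (3 satisfaction metrics here to keep the run short)
in which every unit's innovation SD halves after the change point, but only
the three lowest-baseline units gain in mean — and a dominant hospital-wide
month effect dilutes that gain at the pooled level. The panel report flags
variance reduction per unit and per pooled metric, and Holm-corrects the
mean-change claims.
"""
from implfx import ITSModelConfig, analyze_panel, consistency_scenario

panel = consistency_scenario(seed=3, n_metrics=3)
report = analyze_panel(panel, ITSModelConfig(n_boot=199, seed=0))

frac = report.per_unit["variability_reduced"].mean()
print(f"unit-level 'variability reduced' flags: {frac:.0%} of "
      f"{len(report.per_unit)} unit x metric series")
print(f"pooled variance ratios: "
      f"{[round(v, 3) for v in report.pooled['variance_ratio']]}")
print(f"pooled mean-change flags (Holm across metrics): "
      f"{report.pooled['mean_flag'].tolist()}")
print("\nVariance ratios near 0.25 recover the planted halving of the")
print("innovation SD; the pooled mean change stays unflagged because the")
print("three improving units are diluted by seven flat ones and a shared")
print("hospital-month effect that does not average out.")
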