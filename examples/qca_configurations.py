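"""Configurational (QCA) analysis of implementation conditions.

Simulates 60 clinical units with three implementation conditions and a
planted rule — the outcome occurs exactly when (Readiness AND Structuring)
or Practice holds — plus 5% noise, then recovers the rule by truth-table
minimization and reports necessity of each condition.
"""
from implfx import QCASimParams, analyze_qca, simulate_qca

data = simulate_qca(QCASimParams(
    n_cases=60,
    condition_names=("Readiness", "Structuring", "Practice"),
    planted_solution="Readiness*Structuring + Practice",
    noise_rate=0.05,
    seed=12,
))
solution = analyze_qca(data, freq_cutoff=1, cons_cutoff=0.8)

print(f"minimized sufficient configurations: {solution.expression}")
print(f"solution consistency={solution.consistency:.3f} "
      f"coverage={solution.coverage:.3f}")
print("\nnecessity of single conditions for the outcome:")
print(solution.necessity_report.round(3).to_string(index=False))
print("\nConsistency near 1 means cases with the configuration are (almost)")
print("a subset of cases with the outcome; coverage is the share of the")
print("outcome those configurations account for. A condition with necessity")
print("consistency 1.0 is present whenever the outcome is.")
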