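"""Monte-Carlo operating characteristics of conditional vs marginal tests.

Reproduces the two canonical comparisons: power under a direct treatment
effect, and type-I/type-II behaviour when the effect is purely indirect.
"""

from condde import figure1_scenarios, rejection_rates

spec_a, spec_b = figure1_scenarios()

rep_a = rejection_rates(spec_a, n_replicates=500, alpha=0.05, seed=1)
rep_b = rejection_rates(spec_b, n_replicates=500, alpha=0.05, seed=1)

print(f"Scenario '{rep_a.scenario}' (direct shift on g2):")
print(rep_a.rates.round(3).to_string())
print()
print(f"Scenario '{rep_b.scenario}' (treatment reaches g2 only through g1):")
print(rep_b.rates.round(3).to_string())
print()
print(
    "Direct effect: the conditional test at g2 rejects far more often than\n"
    "the marginal test (it isolates the direct effect against residual\n"
    "noise). Indirect effect: the conditional rate at g2 sits near the\n"
    "nominal 0.05 (its null is true) while the marginal test is dragged to\n"
    "high rejection rates by the g1-mediated signal."
)
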