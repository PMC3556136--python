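"""Test genes for treatment effect conditional on their network parents.

Simulates the two-gene direct-effect scenario (treatment represses the
regulator g1 and directly induces the target g2, with the chain edge
g1 -> g2), then runs the full per-gene testing pipeline both ways.
"""

from condde import Dag, figure1_scenarios, run_all, sample

spec_a, _ = figure1_scenarios(shift_g2=1.0, seed=42)
data = sample(spec_a)
dag = Dag(["g1", "g2"], [("g1", "g2")])

print("Conditional tests (each gene given its parents), Holm-adjusted:")
print(run_all(data, dag, method="conditional").to_string(index=False))
print()
print("Marginal tests (network ignored):")
print(run_all(data, dag, method="marginal").to_string(index=False))
print()
print(
    "g2 carries a direct treatment effect, but its net (marginal) effect is\n"
    "cancelled by the repressed regulator: only the conditional test, which\n"
    "regresses out g1, recovers a small p-value at g2."
)
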