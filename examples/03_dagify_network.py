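"""Break feedback cycles in a TF network by evidence-ordered greedy insertion.

Builds a small transcription-factor network with a 2-cycle, scores each
TF->TF edge by the t-test p-value of its regression coefficient, and
rebuilds the graph from the strongest evidence down, skipping edges that
would close a cycle.
"""

import numpy as np
import pandas as pd

from condde import DirectedGraph, ExpressionDataset, score_edges, tf_dagify
from condde.dagify import removed_edges

rng = np.random.default_rng(7)
n = 60
idx = [f"s{i}" for i in range(n)]

# tf1 drives tf2 strongly; the reverse edge is spurious
tf1 = rng.normal(size=n)
tf2 = 1.2 * tf1 + rng.normal(size=n)
tg1 = 0.8 * tf2 + rng.normal(size=n)
data = ExpressionDataset(
    pd.DataFrame({"tf1": tf1, "tf2": tf2, "tg1": tg1}, index=idx),
    pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=idx),
)

g0 = DirectedGraph(edges=[("tf1", "tf2"), ("tf2", "tf1"), ("tf2", "tg1")])
evidence = score_edges(g0, data)
print("Edge evidence (coefficient t-test p-values):")
for ev in sorted(evidence, key=lambda e: e.p_value):
    print(f"  {ev.edge[0]} -> {ev.edge[1]}: p = {ev.p_value:.3g}")

dag = tf_dagify(g0, {"tf1", "tf2"}, data)
print("\nDAG edges after cycle breaking:", sorted(dag.edges))
print("Removed:", [e.edge for e in removed_edges(g0, dag, evidence)])
print(
    "\nThe 2-cycle between the TFs is broken by dropping the edge with the\n"
    "weaker regression evidence; the TF -> target edge is never touched."
)
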