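"""Edge scoring and greedy DAG-ification of cyclic regulatory networks."""

import numpy as np
import pytest
from scipy import stats

from condde import (
    Dag,
    DirectedGraph,
    EdgeEvidence,
    as_dag,
    greedy_acyclic,
    score_edges,
    tf_dagify,
)
from condde.errors import CondDEError

from conftest import make_dataset


def _random_dataset(genes, n, rng):
    return make_dataset(
        {g: rng.normal(size=n) for g in genes},
        np.repeat(["a", "b"], n // 2),
    )


class TestScoreEdges:
    def test_single_parent_equals_simple_regression_p(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        data = make_dataset({"u": x, "v": y}, np.repeat(["a", "b"], 15))
        g = DirectedGraph(edges=[("u", "v")])
        [ev] = score_edges(g, data)
        lr = stats.linregress(x, y)
        assert ev.edge == ("u", "v")
        assert ev.p_value == pytest.approx(lr.pvalue, rel=1e-9)

    def test_predictive_parent_scores_small_p(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 200
            x = rng.normal(size=n)
            y = 2.0 * x + rng.normal(size=n)
            data = make_dataset({"u": x, "v": y}, np.repeat(["a", "b"], 100))
            [ev] = score_edges(DirectedGraph(edges=[("u", "v")]), data)
            hits += ev.p_value < 0.01
        assert hits >= 0.95 * reps

    def test_null_parent_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            data = _random_dataset(["u", "v"], 50, rng)
            [ev] = score_edges(DirectedGraph(edges=[("u", "v")]), data)
            ps.append(ev.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_target_scores_one_with_warning(self):
        data = make_dataset({"u": range(6), "v": [1.0] * 6},
                            ["a", "a", "a", "b", "b", "b"])
        with pytest.warns(UserWarning, match="constant"):
            [ev] = score_edges(DirectedGraph(edges=[("u", "v")]), data)
        assert ev.p_value == 1.0

    def test_high_in_degree_falls_back_to_single_parent(self):
        rng = np.random.default_rng(4)
        n = 6
        genes = [f"p{i}" for i in range(6)] + ["v"]
        data = _random_dataset(genes, n, rng)
        g = DirectedGraph(edges=[(f"p{i}", "v") for i in range(6)])
        with pytest.warns(UserWarning, match="falling back"):
            evidence = score_edges(g, data)
        assert len(evidence) == 6
        assert all(0 <= e.p_value <= 1 for e in evidence)


def greedy_oracle(edges_with_p, nodes):
    """Independent simulation of the insertion order using a dict-based
    DFS cycle check (no networkx)."""
    adj = {n: set() for n in nodes}
    kept = []
    for (u, v), _ in sorted(edges_with_p, key=lambda t: (t[1], t[0])):
        stack, seen = [v], {v}
        cyc = False
        while stack:
            x = stack.pop()
            if x == u:
                cyc = True
                break
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if not cyc:
            adj[u].add(v)
            kept.append((u, v))
    return set(kept)


class TestGreedyAcyclic:
    def test_acyclic_input_unchanged(self, chain_dag):
        ev = [EdgeEvidence(e, 0.5) for e in chain_dag.edges]
        out = greedy_acyclic(chain_dag, ev)
        assert out.edges == chain_dag.edges

    def test_two_cycle_keeps_stronger_edge(self):
        g = DirectedGraph(edges=[("a", "b"), ("b", "a")])
        ev = [EdgeEvidence(("a", "b"), 0.01), EdgeEvidence(("b", "a"), 0.02)]
        assert greedy_acyclic(g, ev).edges == {("a", "b")}

    def test_three_cycle_drops_weakest(self):
        g = DirectedGraph(edges=[("a", "b"), ("b", "c"), ("c", "a")])
        ev = [
            EdgeEvidence(("a", "b"), 0.01),
            EdgeEvidence(("b", "c"), 0.02),
            EdgeEvidence(("c", "a"), 0.03),
        ]
        assert greedy_acyclic(g, ev).edges == {("a", "b"), ("b", "c")}

    def test_missing_evidence_rejected(self):
        g = DirectedGraph(edges=[("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="evidence"):
            greedy_acyclic(g, [EdgeEvidence(("a", "b"), 0.1)])

    def test_output_acyclic_and_greedy_maximal(self):
        rng = np.random.default_rng(6)
        names = [f"n{i}" for i in range(8)]
        for _ in range(40):
            edges = {
                (u, v)
                for u in names
                for v in names
                if u != v and rng.random() < 0.25
            }
            g = DirectedGraph(names, edges)
            ev = [EdgeEvidence(e, float(rng.uniform())) for e in sorted(edges)]
            dag = greedy_acyclic(g, ev)
            as_dag(dag)  # validates acyclicity
            # maximality: every excluded edge closes a cycle if re-added
            for e in edges - dag.edges:
                with pytest.raises(CondDEError):
                    as_dag(DirectedGraph(names, dag.edges | {e}))

    def test_matches_order_simulation_oracle_on_small_graphs(self):
        rng = np.random.default_rng(7)
        names = [f"n{i}" for i in range(6)]
        for _ in range(60):
            edges = sorted(
                (u, v) for u in names for v in names
                if u != v and rng.random() < 0.3
            )
            pvals = rng.uniform(size=len(edges))
            g = DirectedGraph(names, edges)
            ev = [EdgeEvidence(e, float(p)) for e, p in zip(edges, pvals)]
            expected = greedy_oracle(list(zip(edges, pvals)), names)
            assert greedy_acyclic(g, ev).edges == expected


class TestTfDagify:
    def _data(self, genes, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return _random_dataset(genes, n, rng)

    def test_acyclic_input_identical_edges(self):
        g0 = DirectedGraph(edges=[("tf1", "tf2"), ("tf2", "tg1"), ("tf1", "tg2")])
        data = self._data(["tf1", "tf2", "tg1", "tg2"])
        out = tf_dagify(g0, {"tf1", "tf2"}, data)
        assert out.edges == g0.edges

    def test_mutual_tfs_lose_exactly_one_edge(self):
        g0 = DirectedGraph(
            edges=[("tf1", "tf2"), ("tf2", "tf1"),
                   ("tf1", "ta"), ("tf1", "tb"), ("tf2", "tc"), ("tf2", "td")]
        )
        data = self._data(["tf1", "tf2", "ta", "tb", "tc", "td"])
        out = tf_dagify(g0, {"tf1", "tf2"}, data)
        removed = g0.edges - out.edges
        assert len(removed) == 1
        assert removed <= {("tf1", "tf2"), ("tf2", "tf1")}
        # all TF->TG edges kept
        assert {e for e in g0.edges if e[1] not in {"tf1", "tf2"}} <= out.edges

    def test_never_removes_edges_into_non_tfs(self):
        rng = np.random.default_rng(12)
        tfs = [f"tf{i}" for i in range(4)]
        tgs = [f"tg{i}" for i in range(5)]
        edges = {(u, v) for u in tfs for v in tfs if u != v and rng.random() < 0.5}
        edges |= {(u, v) for u in tfs for v in tgs if rng.random() < 0.5}
        g0 = DirectedGraph(tfs + tgs, edges)
        data = self._data(tfs + tgs, seed=13)
        out = tf_dagify(g0, set(tfs), data)
        removed = g0.edges - out.edges
        assert all(v in tfs for _, v in removed)

    def test_non_tf_source_rejected(self):
        g0 = DirectedGraph(edges=[("tg1", "tf1")])
        data = self._data(["tg1", "tf1"])
        with pytest.raises(CondDEError, match="non-TF"):
            tf_dagify(g0, {"tf1"}, data)
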