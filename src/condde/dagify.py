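"""Greedy DAG-ification of cyclic regulatory networks.

Transcription-factor networks assembled from databases routinely contain
feedback cycles (TFs regulating each other), but the conditional testing
framework needs a DAG. The construction implemented here mirrors the
global-TF-network workflow: score every edge of the cyclic TF subgraph
by the evidence its coefficient carries in a per-target regression, then
rebuild the graph greedily from the strongest-evidence edge down,
skipping any edge that would close a directed cycle, and finally re-attach
the acyclic TF->target-gene fringe.

This is deliberately a greedy heuristic ordered by statistical evidence,
not a minimum-feedback-arc-set optimization.
"""

from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .data import ExpressionDataset
from .errors import CondDEError
from .graphs import Dag, DirectedGraph, as_dag, induced_subgraph

__all__ = ["EdgeEvidence", "score_edges", "greedy_acyclic", "tf_dagify", "removed_edges"]


class EdgeEvidence(NamedTuple):
    edge: tuple[str, str]
    p_value: float


def _coefficient_pvalues(y: np.ndarray, parents: list[str], data) -> dict[str, float]:
    """Two-sided t-test p-value for each parent's coefficient in the OLS
    regression of ``y`` on intercept + parents (treatment excluded: the
    network describes the steady-state structure)."""
    n = y.size
    X = np.column_stack([np.ones(n)] + [data.gene_values(p) for p in parents])
    q = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < q:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - q
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    out = {}
    for j, p in enumerate(parents, start=1):
        if se[j] == 0.0:
            out[p] = 0.0 if beta[j] != 0 else 1.0
        else:
            t = beta[j] / se[j]
            out[p] = float(2.0 * stats.t.sf(abs(t), df))
    return out


def score_edges(g: DirectedGraph, data: ExpressionDataset) -> list[EdgeEvidence]:
    """Evidence for each edge: the p-value of its coefficient in the
    regression of the target on all its in-network parents.

    Degenerate targets (constant expression) get p = 1 for all incoming
    edges with a warning. When a target has more parents than the sample
    size supports (|parents| > N - 2), the full regression is rank
    deficient; its parents are scored by fallback single-parent simple
    regressions instead, again with a warning.
    """
    missing = g.nodes - set(data.values.columns)
    if missing:
        raise KeyError(f"network genes absent from data: {sorted(missing)[:5]}")
    by_target: dict[str, list[str]] = {}
    for u, v in sorted(g.edges):
        by_target.setdefault(v, []).append(u)
    evidence: list[EdgeEvidence] = []
    n = data.n_samples
    for target, parents in sorted(by_target.items()):
        y = data.gene_values(target)
        if np.ptp(y) == 0.0:
            warnings.warn(
                f"target {target!r} has constant expression; scoring its "
                f"{len(parents)} incoming edge(s) with p = 1",
                stacklevel=2,
            )
            evidence.extend(EdgeEvidence((p, target), 1.0) for p in parents)
            continue
        if len(parents) > n - 2:
            warnings.warn(
                f"target {target!r} has {len(parents)} parents with only {n} "
                "samples; falling back to single-parent regressions",
                stacklevel=2,
            )
            for p in parents:
                pv = _coefficient_pvalues(y, [p], data)[p]
                evidence.append(EdgeEvidence((p, target), pv))
            continue
        try:
            pvals = _coefficient_pvalues(y, parents, data)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"collinear parents of {target!r}; falling back to "
                "single-parent regressions",
                stacklevel=2,
            )
            pvals = {p: _coefficient_pvalues(y, [p], data)[p] for p in parents}
        evidence.extend(EdgeEvidence((p, target), pvals[p]) for p in parents)
    return evidence


def greedy_acyclic(g: DirectedGraph, evidence: Iterable[EdgeEvidence]) -> Dag:
    """Rebuild ``g`` from the null graph, inserting edges in increasing
    p-value order (ties broken lexicographically on (source, target)) and
    skipping exactly those that would create a directed cycle.

    Every edge of ``g`` must appear in ``evidence``.
    """
    ev = {e.edge: e.p_value for e in evidence}
    missing = g.edges - set(ev)
    if missing:
        raise ValueError(f"evidence missing for edges: {sorted(missing)[:5]}")
    order = sorted(g.edges, key=lambda e: (ev[e], e))
    succ: dict[str, set[str]] = {n: set() for n in g.nodes}
    kept: set[tuple[str, str]] = set()

    def reaches(start: str, goal: str) -> bool:
        stack, seen = [start], {start}
        while stack:
            node = stack.pop()
            if node == goal:
                return True
            for nxt in succ[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    for u, v in order:
        # adding u->v closes a cycle iff v already reaches u
        if not reaches(v, u):
            succ[u].add(v)
            kept.add((u, v))
    return Dag(g.nodes, kept)


def tf_dagify(
    g0: DirectedGraph, tf_set: Iterable[str], data: ExpressionDataset
) -> Dag:
    """DAG-ify a TF->target network by breaking cycles inside the TF core.

    Every edge source must be a transcription factor. The TF-induced
    subgraph (which holds all cycles) is DAG-ified by
    :func:`greedy_acyclic` over :func:`score_edges` evidence, and the
    remaining TF->non-TF nodes and edges are re-attached unchanged; the
    result is acyclic because non-TF nodes have no outgoing edges.
    """
    tfs = frozenset(tf_set)
    bad = [e for e in sorted(g0.edges) if e[0] not in tfs]
    if bad:
        raise CondDEError(
            f"edge {bad[0]} has a non-TF source; TF->target semantics violated"
        )
    g1 = induced_subgraph(g0, tfs)
    g2 = greedy_acyclic(g1, score_edges(g1, data))
    kept = (g0.edges - g1.edges) | g2.edges
    return as_dag(DirectedGraph(g0.nodes, kept))


def removed_edges(
    g0: DirectedGraph, dag: Dag, evidence: Iterable[EdgeEvidence] = ()
) -> list[EdgeEvidence]:
    """Edges of the original graph absent from the DAG, with their
    evidence p-values where known (else NaN)."""
    ev = {e.edge: e.p_value for e in evidence}
    return [
        EdgeEvidence(e, ev.get(e, float("nan")))
        for e in sorted(g0.edges - dag.edges)
    ]
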