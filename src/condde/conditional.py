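"""Per-gene conditional and marginal tests of treatment effect.

The core procedure: for each gene g with network parents S = pa(g), test
whether expression is independent of treatment given the parents,

    H_g :  x_g  indep  x_T | x_S,

by an F-test that all k-1 treatment-indicator coefficients vanish in the
regression of x_g on intercept + x_S + treatment,

    F = [(RSS_S - RSS_{S+T}) / (k-1)] / [RSS_{S+T} / (N - |S| - k)].

For binary treatment this is the square of the usual t-statistic. The
marginal test is the special case S = empty (the edgeless network), i.e.
one-way ANOVA / the two-sample pooled-variance t-test. Each gene's test
depends only on its own parent set, so tests decouple across genes. A
permutation fallback re-randomizes treatment labels for data where the
Gaussian assumption is in doubt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .graphs import Dag, restrict_to_measured
from . import multiplicity as mult

__all__ = [
    "GeneTestResult",
    "conditional_test",
    "marginal_test",
    "permutation_test",
    "run_all",
    "results_to_frame",
]

RESULT_COLUMNS = [
    "gene",
    "n_parents",
    "parents",
    "statistic",
    "df_num",
    "df_den",
    "p_raw",
    "p_adjusted",
    "status",
]


@dataclass(frozen=True)
class GeneTestResult:
    gene: str
    parents_used: tuple[str, ...]
    statistic: float
    df_num: int
    df_den: int
    p_raw: float
    method: str  # conditional-F | marginal-F | permutation
    status: str = "ok"  # ok | skipped
    reason: str = ""
    p_adjusted: float | None = None


def _skipped(gene, parent_list, method, reason) -> GeneTestResult:
    return GeneTestResult(
        gene=gene,
        parents_used=tuple(parent_list),
        statistic=float("nan"),
        df_num=0,
        df_den=0,
        p_raw=float("nan"),
        method=method,
        status="skipped",
        reason=reason,
    )


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _f_statistic(data: ExpressionDataset, gene: str, parent_list: list[str]):
    """(F, df_num, df_den) for the treatment term given the parents."""
    n, k, s = data.n_samples, data.n_levels, len(parent_list)
    y = data.gene_values(gene)
    X0 = np.column_stack(
        [np.ones(n)] + [data.gene_values(p) for p in parent_list]
    )
    X1 = np.hstack([X0, data.treatment_dummies()])
    rss0 = _rss(y, X0)
    rss1 = _rss(y, X1)
    df_num = k - 1
    df_den = n - s - k
    if rss1 <= 0.0:
        # saturated fit: no residual variation to test against
        return float("inf"), df_num, df_den
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return max(f, 0.0), df_num, df_den


def conditional_test(
    data: ExpressionDataset, gene: str, parent_set, method: str = "conditional-F"
) -> GeneTestResult:
    """F-test of gene-vs-treatment independence given the gene's parents.

    Untestable genes (insufficient residual df, constant expression) come
    back with ``status='skipped'`` and a reason instead of raising, so a
    genome-wide run is never derailed by a single degenerate gene.
    """
    if gene not in data.values.columns:
        raise KeyError(gene)
    parent_list = sorted(parent_set)
    for p in parent_list:
        if p not in data.values.columns:
            raise KeyError(f"parent {p!r} of {gene!r} not in the expression data")
    n, k = data.n_samples, data.n_levels
    df_den = n - len(parent_list) - k
    if df_den < 1:
        return _skipped(gene, parent_list, method, "insufficient residual df")
    if np.ptp(data.gene_values(gene)) == 0.0:
        return _skipped(gene, parent_list, method, "degenerate response")
    f, df_num, df_den = _f_statistic(data, gene, parent_list)
    p = float(stats.f.sf(f, df_num, df_den))
    return GeneTestResult(
        gene=gene,
        parents_used=tuple(parent_list),
        statistic=f,
        df_num=df_num,
        df_den=df_den,
        p_raw=p,
        method=method,
    )


def marginal_test(data: ExpressionDataset, gene: str) -> GeneTestResult:
    """One-way ANOVA F-test of treatment effect, ignoring the network.

    Identical to :func:`conditional_test` with an empty parent set; for
    binary treatment the statistic is the squared pooled-variance
    two-sample t.
    """
    return conditional_test(data, gene, (), method="marginal-F")


def permutation_test(
    data: ExpressionDataset,
    gene: str,
    parent_set,
    n_perm: int = 999,
    seed: int = 0,
) -> GeneTestResult:
    """Permutation version of the conditional test for non-Gaussian data.

    Treatment labels are permuted across samples; the conditional F
    statistic is recomputed per permutation and

        p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    base = conditional_test(data, gene, parent_set, method="permutation")
    if base.status == "skipped":
        return base
    rng = np.random.default_rng(seed)
    t = data.treatment.to_numpy()
    n, k, s = data.n_samples, data.n_levels, len(base.parents_used)
    y = data.gene_values(gene)
    X0 = np.column_stack(
        [np.ones(n)] + [data.gene_values(p) for p in base.parents_used]
    )
    rss0 = _rss(y, X0)  # reduced model has no treatment term: permutation-invariant
    levels = data.levels
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(t)
        dummies = np.column_stack([(perm == lev).astype(float) for lev in levels[1:]])
        rss1 = _rss(y, np.hstack([X0, dummies]))
        if rss1 <= 0.0:
            f = float("inf")
        else:
            f = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - s - k))
        if f >= base.statistic:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return replace(base, p_raw=p)


def run_all(
    data: ExpressionDataset,
    dag: Dag,
    method: str = "conditional",
    multiplicity: str = "holm",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every gene of the network against treatment; adjust p-values.

    The DAG is restricted to measured genes first (with a warning if any
    are dropped). Row order is the DAG's deterministic topological order
    (lexicographic tie-break). Genes skipped as untestable are excluded
    from the multiplicity family -- including hypotheses that can never
    be rejected would distort the step-down adjustment -- and carry their
    reason in the ``status`` column.
    """
    if method not in ("conditional", "marginal", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if multiplicity not in ("holm", "bh", "none"):
        raise ValueError(f"unknown multiplicity correction {multiplicity!r}")
    measured = set(data.values.columns)
    overlap = dag.nodes & measured
    if not overlap:
        raise ValueError("no overlap between network genes and expression data")
    if overlap != dag.nodes:
        warnings.warn(
            f"dropping {len(dag.nodes) - len(overlap)} unmeasured network genes",
            stacklevel=2,
        )
        dag = restrict_to_measured(dag, measured)
    results: list[GeneTestResult] = []
    for gene in dag.topological_order:
        parents = dag.parents(gene) if method != "marginal" else frozenset()
        if method == "permutation":
            res = permutation_test(data, gene, parents, n_perm=n_perm, seed=seed)
        elif method == "conditional":
            res = conditional_test(data, gene, parents)
        else:
            res = marginal_test(data, gene)
        results.append(res)

    ok = [r for r in results if r.status == "ok"]
    if multiplicity != "none" and ok:
        raw = np.array([r.p_raw for r in ok])
        adj = mult.holm_adjust(raw) if multiplicity == "holm" else mult.bh_adjust(raw)
        adjusted = {r.gene: a for r, a in zip(ok, adj)}
    else:
        adjusted = {r.gene: r.p_raw for r in ok}
    results = [
        replace(r, p_adjusted=adjusted.get(r.gene)) if r.status == "ok" else r
        for r in results
    ]
    return results_to_frame(results)


def results_to_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "n_parents": len(r.parents_used),
                "parents": ";".join(r.parents_used),
                "statistic": r.statistic,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p_raw": r.p_raw,
                "p_adjusted": np.nan if r.p_adjusted is None else r.p_adjusted,
                "status": r.status if not r.reason else f"{r.status}: {r.reason}",
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
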