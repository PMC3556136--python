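"""Gaussian Bayesian-network fitting and deviance comparison.

Under the model the joint density of the expression matrix factorizes
over the DAG into one linear regression per gene on its parents; for
genes directly affected by treatment (V_T in the augmented graph) the
regression additionally carries k-1 treatment-indicator columns, i.e. an
additive shift per non-reference level. Maximum likelihood therefore
decomposes into independent per-node OLS fits, with the variance MLE
using divisor N so that differences of maximized log-likelihoods are
exact likelihood-ratio statistics.

The marginal term f(x_T) of the augmented factorization is excluded from
all likelihoods: the analysis conditions on treatment, and the term
cancels in every deviance of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionDataset
from .errors import (
    DegenerateResponseError,
    InsufficientDFError,
    NestingError,
    RankDeficiencyError,
)
from .graphs import AugmentedDag

__all__ = ["NodeFit", "ModelFit", "fit_node", "fit_model", "deviance_test"]

#: relative tolerance below which a tiny negative deviance is treated as
#: floating-point noise from nested fits
DEVIANCE_TOL = 1e-8


@dataclass(frozen=True)
class NodeFit:
    """OLS fit of one gene on its parents (+ optional treatment shifts)."""

    gene: str
    regressors: tuple[str, ...]  # parent genes, then treatment-indicator labels
    intercept: float
    coefficients: np.ndarray  # aligned with ``regressors``
    residual_variance_mle: float  # RSS / N
    rss: float
    n_params: int  # regression parameters incl. intercept (variance excluded)
    log_likelihood: float

    @property
    def n_obs(self) -> int:
        return round(self.rss / self.residual_variance_mle) if self.residual_variance_mle else 0


@dataclass(frozen=True)
class ModelFit:
    graph: AugmentedDag
    node_fits: dict[str, NodeFit]
    total_log_likelihood: float

    @property
    def n_params(self) -> int:
        return sum(f.n_params for f in self.node_fits.values())


def _design(data: ExpressionDataset, parent_list: list[str], include_treatment: bool):
    cols = [np.ones(data.n_samples)]
    names: list[str] = []
    for p in parent_list:
        cols.append(data.gene_values(p))
        names.append(p)
    if include_treatment:
        dummies = data.treatment_dummies()
        for j, lev in enumerate(data.levels[1:]):
            cols.append(dummies[:, j])
            names.append(f"T[{lev}]")
    return np.column_stack(cols), names


def ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and residual sum of squares.

    RSS is computed from the residuals themselves (not the lstsq
    shortcut) so it is well defined also for exactly-fitting designs.
    """
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns"
        )
    resid = y - X @ beta
    return beta, float(resid @ resid)


def gaussian_loglik(n: int, rss: float) -> float:
    """Profile log-likelihood of a Gaussian linear model at sigma^2 = RSS/n."""
    s2 = rss / n
    if s2 <= 0.0:
        raise DegenerateResponseError("zero residual variance; log-likelihood diverges")
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


def fit_node(
    data: ExpressionDataset,
    gene: str,
    parent_set,
    include_treatment: bool = False,
) -> NodeFit:
    """Fit one conditional regression of the factorized likelihood.

    Raises
    ------
    DegenerateResponseError
        if the gene has zero sample variance.
    RankDeficiencyError
        if the design is collinear.
    InsufficientDFError
        if N - 1 - |parents| - include_treatment*(k-1) < 1.
    """
    if gene not in data.values.columns:
        raise KeyError(gene)
    parent_list = sorted(parent_set)
    for p in parent_list:
        if p not in data.values.columns:
            raise KeyError(f"parent {p!r} of {gene!r} not in the expression data")
    n = data.n_samples
    k = data.n_levels
    q = 1 + len(parent_list) + (k - 1 if include_treatment else 0)
    if n - q < 1:
        raise InsufficientDFError(
            f"gene {gene!r}: residual df {n - q} < 1 "
            f"(N={n}, parents={len(parent_list)}, treatment={include_treatment})"
        )
    y = data.gene_values(gene)
    if np.ptp(y) == 0.0:
        raise DegenerateResponseError(f"gene {gene!r} has constant expression")
    X, names = _design(data, parent_list, include_treatment)
    try:
        beta, rss = ols_rss(y, X)
    except RankDeficiencyError as err:
        raise RankDeficiencyError(
            f"gene {gene!r}: collinear design over columns "
            f"['intercept'] + {names}: {err}"
        ) from None
    ll = gaussian_loglik(n, rss)
    return NodeFit(
        gene=gene,
        regressors=tuple(names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        residual_variance_mle=rss / n,
        rss=rss,
        n_params=q,
        log_likelihood=ll,
    )


def fit_model(data: ExpressionDataset, g: AugmentedDag) -> ModelFit:
    """Fit the full factorized model: one node fit per gene in the DAG.

    The treatment term is included exactly for genes in ``g.treated_genes``.
    The total log-likelihood is the sum of node log-likelihoods.
    """
    missing = g.base.nodes - set(data.values.columns)
    if missing:
        raise KeyError(f"network genes absent from data: {sorted(missing)[:5]}")
    fits: dict[str, NodeFit] = {}
    for gene in g.base.topological_order:
        try:
            fits[gene] = fit_node(
                data, gene, g.base.parents(gene), gene in g.treated_genes
            )
        except Exception as err:
            raise type(err)(f"while fitting gene {gene!r}: {err}") from err
    total = sum(f.log_likelihood for f in fits.values())
    return ModelFit(graph=g, node_fits=fits, total_log_likelihood=total)


def deviance_test(fit0: ModelFit, fit1: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance) test of a null model within a richer one.

    Returns ``(deviance, df, p)`` with deviance = 2*(l1 - l0) >= 0,
    df = difference in regression-parameter counts, and p the upper-tail
    chi-square probability. Requires fit0 nested in fit1: same genes and
    data, fit0's edges and treated genes subsets of fit1's.
    """
    g0, g1 = fit0.graph, fit1.graph
    if g0.base.nodes != g1.base.nodes:
        raise NestingError("models are over different gene sets")
    if not (g0.base.edges <= g1.base.edges):
        raise NestingError("null model has edges absent from the alternative")
    if not (g0.treated_genes <= g1.treated_genes):
        raise NestingError("null model has treatment edges absent from the alternative")
    df = fit1.n_params - fit0.n_params
    dev = 2.0 * (fit1.total_log_likelihood - fit0.total_log_likelihood)
    scale = max(1.0, abs(fit1.total_log_likelihood))
    if dev < -DEVIANCE_TOL * scale:
        raise ArithmeticError(
            f"negative deviance {dev} beyond tolerance; nested fits inconsistent"
        )
    dev = max(dev, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(dev, df))
    return dev, df, p
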