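"""Multiple-testing corrections: Holm step-down (FWER) and BH step-up (FDR).

Rejecting hypotheses whose Holm-adjusted p-value falls below alpha
controls the family-wise error rate -- the probability of any false
rejection -- irrespective of which hypotheses are true. The
Benjamini-Hochberg adjustment instead controls the expected proportion
of false rejections among rejections. The numeric adjustments delegate
to statsmodels' multipletests.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["PvalueFamily", "holm_adjust", "bh_adjust", "significant_set"]


class PvalueFamily(NamedTuple):
    """A family of raw p-values with unique labels."""

    labels: tuple[str, ...]
    p_raw: np.ndarray

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "PvalueFamily":
        labels, p = zip(*pairs)
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        return cls(tuple(labels), np.asarray(p, dtype=float))


def _validated(p) -> np.ndarray:
    if isinstance(p, PvalueFamily):
        p = p.p_raw
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("need a one-dimensional family with m >= 1 p-values")
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    In sorted order: adj_(i) = min(1, max_{j<=i} (m-j+1) * p_(j)).
    """
    arr = _validated(p)
    return multipletests(arr, method="holm")[1]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    In sorted order: adj_(i) = min(1, min_{j>=i} m * p_(j) / j); rejecting
    adj < alpha controls the FDR at alpha under independence.
    """
    arr = _validated(p)
    return multipletests(arr, method="fdr_bh")[1]


def significant_set(labels, adjusted, alpha: float) -> set[str]:
    """Labels whose adjusted p-value is strictly below alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    labels = list(labels)
    adjusted = np.asarray(adjusted, dtype=float)
    if len(labels) != adjusted.size:
        raise ValueError("labels and adjusted p-values differ in length")
    return {lab for lab, a in zip(labels, adjusted) if a < alpha}
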