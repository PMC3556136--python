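"""Expression dataset container and file readers.

The canonical in-memory form is a pandas DataFrame of shape
(samples x genes) of continuous values (log-scale intensities are the
intended use) plus an aligned categorical treatment Series with k >= 2
levels. On-disk, expression matrices follow the microarray convention of
genes as rows and samples as columns, first column = gene identifier;
the phenotype table is a TSV/CSV with columns ``sample_id`` and
``treatment``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "read_expression", "read_phenotype"]


def _read_table(path, **kw) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#", **kw)


class ExpressionDataset:
    """N samples x p genes of continuous expression plus treatment labels.

    Missing values are rejected outright -- the model assumes a complete
    matrix and no imputation is attempted. Each treatment level must have
    at least two samples and N >= 3.
    """

    def __init__(self, values: pd.DataFrame, treatment: pd.Series):
        values = values.astype(float)
        treatment = treatment.reindex(values.index)
        if treatment.isna().any():
            missing = list(values.index[treatment.isna()])[:5]
            raise ValueError(f"samples without treatment annotation: {missing}")
        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()[:5]
            raise ValueError(f"missing expression values in genes {bad}; imputation refused")
        if values.shape[0] < 3:
            raise ValueError(f"need N >= 3 samples, got {values.shape[0]}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate gene identifiers: {dup}")
        counts = treatment.astype(str).value_counts()
        if len(counts) < 2:
            raise ValueError("treatment must have at least 2 levels")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"treatment levels with < 2 samples: {small.index.tolist()}")
        self.values = values
        self.treatment = treatment.astype(str)
        # reference level = first in sorted order: deterministic regardless
        # of file row order
        self.levels: tuple[str, ...] = tuple(sorted(counts.index))

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[gene].to_numpy()

    def treatment_dummies(self) -> np.ndarray:
        """N x (k-1) indicator matrix against the reference (first sorted)
        level; column j indicates level ``self.levels[j+1]``."""
        t = self.treatment.to_numpy()
        return np.column_stack(
            [(t == lev).astype(float) for lev in self.levels[1:]]
        )

    def with_treatment(self, treatment: np.ndarray | pd.Series) -> "ExpressionDataset":
        """Same expression values with a replacement treatment vector
        (used by the permutation test)."""
        s = pd.Series(np.asarray(treatment), index=self.values.index)
        return ExpressionDataset(self.values, s)

    @classmethod
    def from_files(cls, expression_path, phenotype_path) -> "ExpressionDataset":
        values = read_expression(expression_path)
        pheno = read_phenotype(phenotype_path)
        missing = values.index.difference(pheno.index)
        if len(missing):
            raise ValueError(
                f"samples missing from phenotype table: {missing.tolist()[:5]}"
            )
        return cls(values, pheno.loc[values.index])

    def __repr__(self):
        return (
            f"ExpressionDataset({self.n_samples} samples x {self.n_genes} genes, "
            f"{self.n_levels} treatment levels)"
        )


def read_expression(path) -> pd.DataFrame:
    """Read a genes-as-rows matrix and return it samples x genes."""
    df = _read_table(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate gene identifiers in {path}: {dup}")
    out = df.T
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_phenotype(path) -> pd.Series:
    """Read the sample annotation table; returns treatment indexed by sample."""
    df = _read_table(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "treatment" not in cols:
        raise ValueError(
            f"phenotype table {path} must have columns sample_id, treatment"
        )
    s = df.set_index(cols["sample_id"])[cols["treatment"]]
    if s.index.duplicated().any():
        raise ValueError(f"duplicate sample_id entries in {path}")
    return s
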