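"""Pearson correlation and absolute-value similarity matrices.

For standardized profiles x_i (mean 0, variance 1, population convention)
the Pearson correlation reduces to r_ij = (1/m) sum_k x_ik x_jk, i.e. a
single matrix product.  The similarity used for thresholding is s_ij =
|r_ij|; the sign of r_ij is kept alongside so that network edges can be
annotated as positive or negative associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import StandardizedTable

__all__ = [
    "CorrelationMatrix",
    "SimilarityMatrix",
    "correlation_matrix",
    "similarity_from_correlation",
]


@dataclass
class CorrelationMatrix:
    """Symmetric OTU x OTU Pearson correlation matrix with unit diagonal."""

    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.otu_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape does not match otu_ids")


@dataclass
class SimilarityMatrix:
    """Elementwise |r| of a correlation matrix, with the signs retained."""

    otu_ids: list[str]
    values: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.signs = np.asarray(self.signs, dtype=int)
        n = len(self.otu_ids)
        if self.values.shape != (n, n) or self.signs.shape != (n, n):
            raise ValueError("similarity matrix shape does not match otu_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "OTU"
        df.to_csv(path, sep="\t")


def correlation_matrix(table: StandardizedTable) -> CorrelationMatrix:
    """Pairwise Pearson correlations between standardized OTU profiles."""
    if table.n_otus < 3:
        raise ValueError("need at least 3 OTUs for correlation analysis")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    x = table.values
    r = (x @ x.T) / table.n_samples
    # symmetrize and clamp floating-point round-off
    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(table.otu_ids), r)


def similarity_from_correlation(corr: CorrelationMatrix) -> SimilarityMatrix:
    """s_ij = |r_ij|, recording sign(r_ij) for edge annotation."""
    return SimilarityMatrix(
        otu_ids=list(corr.otu_ids),
        values=np.abs(corr.values),
        signs=np.sign(corr.values).astype(int),
    )
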