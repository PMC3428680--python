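"""Trait association: OTU significance, Mantel tests, module-trait grids.

The trait-based OTU significance is the squared Pearson correlation between
an OTU's standardized profile and a (standardized) environmental trait,
GS_ih = cor(x_i, T_h)^2.  Network structure is related to traits by Mantel
tests between the Euclidean distance matrix of GS values and the distance
matrix of node connectivities; the partial Mantel test controls a third
distance matrix by the method of residuals.  Mantel p-values are one-tailed
(greater), the convention of the classic vegan-style implementations, with
p = (1 + #{permuted r >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import StandardizedTable, TraitTable

__all__ = [
    "GSMatrix",
    "MantelResult",
    "otu_significance",
    "gs_topology_correlation",
    "mantel_test",
    "partial_mantel_test",
    "module_trait_correlations",
    "gs_distance_matrix",
    "connectivity_distance_matrix",
]

MIN_PAIRWISE = 3


@dataclass
class GSMatrix:
    """OTU x trait matrix of squared correlations, NaN where undefined."""

    otu_ids: list[str]
    trait_names: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.trait_names)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    partial: bool = False
    controlled: str | None = None
    flag: str = ""


def _pairwise_corr(x: np.ndarray, t: np.ndarray) -> float:
    """Pearson r with pairwise-complete observations; NaN if undefined."""
    ok = ~np.isnan(t)
    if ok.sum() < MIN_PAIRWISE:
        return np.nan
    xv, tv = x[ok], t[ok]
    if xv.std() == 0 or tv.std() == 0:
        return np.nan
    return float(np.corrcoef(xv, tv)[0, 1])


def otu_significance(std_table: StandardizedTable, traits: TraitTable) -> GSMatrix:
    """GS_ih = cor(x_i, T_h)^2 over the shared samples.

    Traits are standardized first if they are not already; missing trait
    values are handled pairwise (at least 3 complete pairs, else NaN).
    """
    traits = traits.align_to(std_table.sample_ids)
    if traits.n_samples < MIN_PAIRWISE:
        raise ValueError("need at least 3 shared samples")
    if not traits.standardized:
        traits = traits.standardize()
    # std_table columns restricted to the shared samples, trait order
    pos = {s: i for i, s in enumerate(std_table.sample_ids)}
    cols = [pos[s] for s in traits.sample_ids]
    x = std_table.values[:, cols]
    gs = np.empty((std_table.n_otus, len(traits.trait_names)))
    for h in range(len(traits.trait_names)):
        t = traits.values[:, h]
        for i in range(x.shape[0]):
            r = _pairwise_corr(x[i], t)
            gs[i, h] = r**2 if not np.isnan(r) else np.nan
    undefined = [
        traits.trait_names[h] for h in range(gs.shape[1]) if np.isnan(gs[:, h]).all()
    ]
    if undefined:
        warnings.warn(f"GS undefined for constant/empty trait(s): {undefined}")
    return GSMatrix(list(std_table.otu_ids), list(traits.trait_names), gs)


def gs_topology_correlation(
    gs_column: np.ndarray, connectivity: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of GS against node connectivity."""
    gs_column = np.asarray(gs_column, dtype=float)
    connectivity = np.asarray(connectivity, dtype=float)
    if gs_column.size != connectivity.size or gs_column.size < 4:
        raise ValueError("need aligned vectors of length >= 4")
    if gs_column.std() == 0 or connectivity.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(gs_column, connectivity)
    return float(r), float(p)


def _check_distance(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _mantel_r(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    Dx: np.ndarray, Dy: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> MantelResult:
    """Mantel test: Pearson correlation of the lower triangles, permutation
    p-value from jointly permuting rows/columns of the second matrix."""
    Dx = _check_distance(Dx, "Dx")
    Dy = _check_distance(Dy, "Dy")
    if Dx.shape != Dy.shape:
        raise ValueError("distance matrices must have the same dimension")
    n = Dx.shape[0]
    iu = np.triu_indices(n, 1)
    x, y = Dx[iu], Dy[iu]
    r = _mantel_r(x, y)
    if np.isnan(r):
        return MantelResult(np.nan, np.nan, n_perm, seed, flag="constant distance matrix")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = Dy[np.ix_(perm, perm)][iu]
        rp = _mantel_r(x, yp)
        if not np.isnan(rp) and rp >= r:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r, p, n_perm, seed)


def _residuals(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(on, v, 1)
    return v - (slope * on + intercept)


def partial_mantel_test(
    Dx: np.ndarray,
    Dy: np.ndarray,
    Dz: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    controlled: str = "Dz",
) -> MantelResult:
    """Partial Mantel test of Dx vs Dy controlling for Dz.

    Method of residuals: the triangles of Dx and Dy are each regressed on
    Dz's triangle and their residuals correlated; permutations act on Dx's
    rows/columns (residuals recomputed per permutation).
    """
    Dx = _check_distance(Dx, "Dx")
    Dy = _check_distance(Dy, "Dy")
    Dz = _check_distance(Dz, "Dz")
    if not Dx.shape == Dy.shape == Dz.shape:
        raise ValueError("distance matrices must have the same dimension")
    n = Dx.shape[0]
    iu = np.triu_indices(n, 1)
    x, y, z = Dx[iu], Dy[iu], Dz[iu]
    if x.std() == 0 or y.std() == 0 or z.std() == 0:
        return MantelResult(
            np.nan, np.nan, n_perm, seed, partial=True, controlled=controlled,
            flag="constant distance matrix",
        )
    # residual variance tolerances are relative: an input affinely
    # identical to the control leaves only ~1e-16 regression round-off
    ry = _residuals(y, z)
    if ry.std() <= 1e-10 * y.std():
        return MantelResult(
            0.0, np.nan, n_perm, seed, partial=True, controlled=controlled,
            flag="zero residual variance",
        )
    rx = _residuals(x, z)
    if rx.std() <= 1e-10 * x.std():
        return MantelResult(
            0.0, np.nan, n_perm, seed, partial=True, controlled=controlled,
            flag="zero residual variance",
        )
    r = _mantel_r(rx, ry)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = Dx[np.ix_(perm, perm)][iu]
        rxp = _residuals(xp, z)
        rp = _mantel_r(rxp, ry)
        if not np.isnan(rp) and rp >= r:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r, p, n_perm, seed, partial=True, controlled=controlled)


def gs_distance_matrix(gs: GSMatrix, traits: list[str] | None = None) -> np.ndarray:
    """Euclidean distances between OTUs over the selected GS columns."""
    df = gs.to_frame()
    if traits is not None:
        df = df[traits]
    vals = df.to_numpy(float)
    if np.isnan(vals).any():
        keep = ~np.isnan(vals).any(axis=0)
        vals = vals[:, keep]
    return squareform(pdist(vals, metric="euclidean"))


def connectivity_distance_matrix(connectivity: np.ndarray) -> np.ndarray:
    """|k_i - k_j| (one-dimensional Euclidean distance)."""
    k = np.asarray(connectivity, dtype=float).reshape(-1, 1)
    return squareform(pdist(k, metric="euclidean"))


def module_trait_correlations(
    eigengenes: pd.DataFrame, traits: TraitTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p per (module eigengene, trait) cell."""
    shared = [s for s in eigengenes.columns if s in traits.sample_ids]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    traits = traits.align_to(list(eigengenes.columns))
    e = eigengenes[traits.sample_ids].to_numpy(float)
    r_out = pd.DataFrame(index=eigengenes.index, columns=traits.trait_names, dtype=float)
    p_out = pd.DataFrame(index=eigengenes.index, columns=traits.trait_names, dtype=float)
    for h, name in enumerate(traits.trait_names):
        t = traits.values[:, h]
        ok = ~np.isnan(t)
        for b, row in zip(eigengenes.index, e):
            if ok.sum() < 4 or t[ok].std() == 0 or row[ok].std() == 0:
                r_out.loc[b, name] = np.nan
                p_out.loc[b, name] = np.nan
                continue
            r, p = stats.pearsonr(row[ok], t[ok])
            r_out.loc[b, name] = float(r)
            p_out.loc[b, name] = float(p)
    return r_out, p_out
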