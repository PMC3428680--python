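"""Module eigengenes: SVD summary profiles, variance explained, membership.

A module's standardized member matrix X^b (n_b x m) is decomposed as
X^b = U D V^T (economy SVD; when n_b < m this is the thin decomposition).
The module eigengene E^b is the leading right-singular vector — the sample
profile that best summarizes the module — with its arbitrary SVD sign fixed
so the mean correlation with member profiles is positive.  The variance
explained is Phi_b = d_1^2 / sum_q d_q^2, and since the rows of X^b are
standardized this equals the leading-eigenvalue share of the member
correlation matrix (PCA and SVD coincide).  Module membership MM_i is the
Pearson correlation of member i's profile with E^b.

Eigengene correlations across modules define the eigengene network;
average-linkage clustering on dissimilarity 1 - r groups modules into
meta-modules below a cut height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform

from .tables import StandardizedTable

__all__ = [
    "EigengeneSet",
    "module_eigengene",
    "module_membership",
    "eigengene_network",
    "eigengene_analysis",
]

#: warn (never fail) when an eigengene explains less variance than this
LOW_VARIANCE_WARN = 0.30


@dataclass
class EigengeneSet:
    """Per-module eigengenes with variance explained and memberships."""

    eigengenes: pd.DataFrame  # modules x samples
    variance_explained: dict[int, float]
    memberships: dict[int, pd.Series]  # module -> MM per member OTU
    correlation: pd.DataFrame | None = None  # module x module eigengene r
    meta_modules: dict[int, int] | None = None  # module -> meta-module label
    dendrogram_order: list[int] | None = None


def _pearson_rows(rows: np.ndarray, profile: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(pc)
    denom = np.where(denom > 0, denom, np.inf)
    return np.clip(rc @ pc / denom, -1.0, 1.0)


def module_eigengene(
    std_table: StandardizedTable, members: list[str]
) -> tuple[np.ndarray, float]:
    """Leading right-singular vector and variance explained for a module.

    Returns (E^b, Phi_b); E^b has unit norm and length m.
    """
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members for eigengene analysis")
    sub = std_table.subset(members)
    x = sub.values
    u, d, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    phi = float(d[0] ** 2 / (d**2).sum())
    mm = _pearson_rows(x, e)
    if mm.mean() < 0:
        e = -e
    if phi < LOW_VARIANCE_WARN:
        warnings.warn(
            f"module eigengene explains only {phi:.1%} of member variance"
        )
    return e, phi


def module_membership(std_table: StandardizedTable, eigengene: np.ndarray) -> pd.Series:
    """Pearson correlation of each profile with the eigengene."""
    e = np.asarray(eigengene, dtype=float)
    if e.size != std_table.n_samples:
        raise ValueError("eigengene length does not match the number of samples")
    mm = _pearson_rows(std_table.values, e)
    return pd.Series(mm, index=std_table.otu_ids, name="MM")


def eigengene_network(
    eigengenes: pd.DataFrame, cut_height: float = 0.3
) -> tuple[pd.DataFrame, list[int], dict[int, int]]:
    """Eigengene correlation matrix, dendrogram order and meta-modules.

    Average-linkage clustering on dissimilarity 1 - r; meta-modules are the
    branches below ``cut_height``.
    """
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 eigengenes")
    labels = list(eigengenes.index)
    r = np.corrcoef(eigengenes.to_numpy(float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=labels, columns=labels)
    diss = 1.0 - r
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(diss, checks=False))
    order = [labels[i] for i in leaves_list(link)]
    flat = fcluster(link, t=cut_height, criterion="distance")
    meta = {labels[i]: int(c) for i, c in enumerate(flat)}
    return corr, order, meta


def eigengene_analysis(
    std_table: StandardizedTable,
    module_members: dict[int, list[str]],
    cut_height: float = 0.3,
) -> EigengeneSet:
    """Eigengene summary for every module in ``module_members``."""
    eig_rows = {}
    phis = {}
    mms = {}
    for b, members in sorted(module_members.items()):
        e, phi = module_eigengene(std_table, members)
        eig_rows[b] = e
        phis[b] = phi
        mms[b] = module_membership(std_table.subset(members), e)
    eig_df = pd.DataFrame.from_dict(eig_rows, orient="index", dtype=float)
    eig_df.columns = list(std_table.sample_ids)
    corr = order = meta = None
    if len(eig_rows) >= 2:
        corr, order, meta = eigengene_network(eig_df, cut_height=cut_height)
    return EigengeneSet(
        eigengenes=eig_df,
        variance_explained=phis,
        memberships=mms,
        correlation=corr,
        meta_modules=meta,
        dendrogram_order=order,
    )
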