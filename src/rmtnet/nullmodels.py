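"""Degree-preserving null models and index significance tests.

Maslov-Sneppen rewiring repeatedly swaps the endpoints of two randomly
chosen edges ((a,b),(c,d) -> (a,d),(c,b)), rejecting swaps that would create
self-loops or duplicate edges, so every rewired network keeps the exact node
set, link count and degree sequence of the original.  An ensemble of such
networks (default 100) supplies the null mean and sd of every whole-network
index; the Z-test compares the observed value against the ensemble, and the
Welch t-test compares indices of two networks through their respective
ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .modules import detect_modules
from .topology import Network, global_topology

__all__ = [
    "EnsembleStats",
    "rewire_maslov_sneppen",
    "compare_to_random",
    "compare_networks",
]

logger = logging.getLogger(__name__)


@dataclass
class EnsembleStats:
    """Per-index empirical value vs a degree-preserving random ensemble."""

    table: pd.DataFrame  # index, empirical, mean, sd, Z, p, flag
    ensemble_size: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return self.table


def rewire_maslov_sneppen(
    net: Network,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    attempt_factor: int = 100,
) -> Network:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Targets ``swaps_per_edge * L`` accepted swaps; gives up after
    ``attempt_factor * L`` attempts (a graph like the triangle admits no
    valid swap and comes back unchanged, logged).
    """
    if net.L < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted((u, v))) for u, v in net.graph.edges()]
    edge_set = set(edges)
    L = len(edges)
    target = swaps_per_edge * L
    cap = attempt_factor * L
    accepted = attempts = 0
    while accepted < target and attempts < cap:
        attempts += 1
        i, j = rng.integers(0, L, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        e1 = tuple(sorted((a, d)))
        e2 = tuple(sorted((c, b)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i] = e1
        edges[j] = e2
        edge_set.add(e1)
        edge_set.add(e2)
        accepted += 1
    if accepted < target:
        logger.info(
            "rewiring stopped at %d/%d accepted swaps after %d attempts",
            accepted, target, attempts,
        )
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes())
    g.add_edges_from(edges)
    return Network(g)


def _index_values(net: Network, with_modularity: bool, module_method: str,
                  seed: int | None) -> dict[str, float]:
    vals = global_topology(net).scalar_indices()
    if with_modularity:
        vals["M"] = detect_modules(net, method=module_method, seed=seed).modularity
    return vals


def compare_to_random(
    net: Network,
    n_random: int = 100,
    seed: int | None = None,
    with_modularity: bool = True,
    module_method: str = "fast_greedy",
    swaps_per_edge: int = 10,
) -> EnsembleStats:
    """Z-test of whole-network indices against a Maslov-Sneppen ensemble.

    Every index (the 13 whole-network scalars, plus modularity M when
    requested) is recomputed on each of ``n_random`` rewired networks.
    Indices fully determined by the degree sequence (avgK, D, W on connected
    ensembles, ...) have zero ensemble spread; they get Z = 0 when the
    empirical value equals the ensemble mean and are flagged undefined
    otherwise.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_random)
    empirical = _index_values(net, with_modularity, module_method, seed)
    rows = []
    for s in child_seeds:
        rnd = rewire_maslov_sneppen(net, swaps_per_edge=swaps_per_edge, seed=int(s))
        rows.append(_index_values(rnd, with_modularity, module_method, int(s)))
    ensemble = pd.DataFrame(rows)
    out = []
    for name in empirical:
        emp = empirical[name]
        mean = float(ensemble[name].mean())
        sd = float(ensemble[name].std(ddof=1))
        # an ensemble of bitwise-equal values can report sd ~ 1e-15 from
        # round-off in the mean; treat that as a degenerate (degree-
        # determined) index
        if sd > 1e-10 * max(1.0, abs(mean)):
            z = (emp - mean) / sd
            p = 2.0 * stats.norm.sf(abs(z))
            flag = ""
        elif abs(emp - mean) <= 1e-9 * max(1.0, abs(mean)):
            z, p, flag = 0.0, 1.0, "degree-determined"
        else:
            z, p, flag = np.nan, np.nan, "zero ensemble sd"
        out.append((name, emp, mean, sd, z, p, flag))
    table = pd.DataFrame(
        out, columns=["index", "empirical", "rand_mean", "rand_sd", "Z", "p", "flag"]
    ).set_index("index")
    return EnsembleStats(table=table, ensemble_size=n_random, seed=seed)


def compare_networks(stats_a: EnsembleStats, stats_b: EnsembleStats) -> pd.DataFrame:
    """Welch t-test per index between two networks, using each network's
    random-ensemble mean/sd as the dispersion estimate."""
    a, b = stats_a.table, stats_b.table
    shared = [i for i in a.index if i in b.index]
    rows = []
    for name in shared:
        m1, s1, n1 = a.loc[name, "rand_mean"], a.loc[name, "rand_sd"], stats_a.ensemble_size
        m2, s2, n2 = b.loc[name, "rand_mean"], b.loc[name, "rand_sd"], stats_b.ensemble_size
        v1, v2 = s1**2 / n1, s2**2 / n2
        if v1 + v2 == 0:
            if abs(m1 - m2) <= 1e-12:
                rows.append((name, 0.0, np.nan, 1.0, "zero variance"))
            else:
                rows.append((name, np.nan, np.nan, np.nan, "zero variance, unequal means"))
            continue
        t = (m1 - m2) / np.sqrt(v1 + v2)
        dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((name, float(t), float(dof), float(p), ""))
    return pd.DataFrame(rows, columns=["index", "t", "dof", "p", "flag"]).set_index("index")
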