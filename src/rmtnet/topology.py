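"""Network construction and topological characterization.

The final network is unweighted: two OTUs are linked when their abundance
similarity |r| meets the RMT-determined threshold.  Per-node indices:
connectivity k, stress centrality SC, betweenness B, eigenvector centrality
EC, clustering coefficient CC, vulnerability V.  Whole-network indices:
average connectivity, average geodesic distance GD, geodesic efficiency E,
harmonic geodesic distance HD = 1/E, centralizations of degree/betweenness/
stress/eigenvector centrality, density, average clustering coefficient,
transitivity, connectedness, plus power-law (scale-free) and clustering-
coefficient scaling-law (hierarchy) fits.

Conventions (declared once, used consistently): shortest-path sums run over
unordered node pairs {j, k} with j != k != i; GD averages over reachable
pairs only while efficiency uses 1/d = 0 for unreachable pairs, making HD
the disconnection-safe companion; centralizations are normalized by degree
bound (n-1)(n-2) for CD and by the same-size star-graph maxima (computed
numerically) for CB, CS and CE; eigenvector centrality lives on the largest
connected component (unit Euclidean norm) and is 0 elsewhere; CC_i = 0 for
nodes with fewer than 2 neighbours.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .similarity import SimilarityMatrix
from .tables import AbundanceTable

__all__ = [
    "Network",
    "FitResult",
    "GlobalTopology",
    "build_network",
    "node_topology",
    "global_topology",
    "fit_power_law",
    "fit_scaling_law",
    "noise_robustness",
]


@dataclass
class Network:
    """Undirected unweighted network over OTUs with at least one edge.

    Edge attributes: ``similarity`` (the |r| value that created the edge)
    and ``sign`` (+1/-1, the sign of the underlying correlation).
    """

    graph: nx.Graph

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes())

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def L(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, d))
        return sorted(out, key=lambda t: (t[0], t[1]))

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree())


@dataclass
class FitResult:
    """Log-log OLS fit of a decaying relation y ~ x^-exponent."""

    exponent: float
    r2: float
    ok: bool
    n_points: int


@dataclass
class GlobalTopology:
    n: int
    L: int
    avg_k: float
    gd: float
    efficiency: float
    hd: float
    cd: float
    cb: float
    cs: float
    ce: float
    density: float
    avg_cc: float
    transitivity: float
    connectedness: float
    unreachable_pairs: int
    power_law: FitResult
    scaling_law: FitResult

    def scalar_indices(self) -> dict[str, float]:
        """The 13 scalar whole-network indices (fits excluded)."""
        return {
            "avgK": self.avg_k,
            "GD": self.gd,
            "E": self.efficiency,
            "HD": self.hd,
            "CD": self.cd,
            "CB": self.cb,
            "CS": self.cs,
            "CE": self.ce,
            "D": self.density,
            "avgCC": self.avg_cc,
            "Trans": self.transitivity,
            "Con": self.connectedness,
            "W": float(self.unreachable_pairs),
        }


def build_network(S: SimilarityMatrix, s_t: float) -> Network:
    """Link every OTU pair with s_ij >= s_t; drop isolated OTUs."""
    if not 0.0 < s_t <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    vals = S.values
    n = len(S.otu_ids)
    iu, ju = np.triu_indices(n, 1)
    hit = vals[iu, ju] >= s_t
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(
            S.otu_ids[i],
            S.otu_ids[j],
            similarity=float(vals[i, j]),
            sign=int(S.signs[i, j]) if S.signs[i, j] != 0 else 1,
        )
    if g.number_of_edges() == 0:
        raise ValueError(f"empty network at threshold {s_t}")
    return Network(g)


def _adjacency(net: Network) -> tuple[list[str], list[list[int]]]:
    nodes = net.node_ids
    index = {u: i for i, u in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for u, v in net.graph.edges():
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    return nodes, adj


def _bfs_counts(adj: list[list[int]], s: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-source distances and shortest-path counts (unweighted BFS)."""
    n = len(adj)
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[s] = 0.0
    sigma[s] = 1.0
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if math.isinf(dist[w]):
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _all_pairs(adj: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    n = len(adj)
    D = np.empty((n, n))
    Sg = np.empty((n, n))
    for s in range(n):
        D[s], Sg[s] = _bfs_counts(adj, s)
    return D, Sg


def _betweenness_stress(D: np.ndarray, Sg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness and stress centrality over unordered pairs, endpoints
    excluded: a pair {s, t} contributes sigma_sv * sigma_vt paths through v
    whenever d(s,v) + d(v,t) = d(s,t)."""
    n = D.shape[0]
    B = np.zeros(n)
    SC = np.zeros(n)
    for v in range(n):
        onpath = (D[:, v][:, None] + D[v, :][None, :]) == D
        onpath[v, :] = False
        onpath[:, v] = False
        np.fill_diagonal(onpath, False)
        through = Sg[:, v][:, None] * Sg[v, :][None, :]
        counts = np.where(onpath, through, 0.0)
        SC[v] = counts.sum() / 2.0
        denom = np.where(Sg > 0, Sg, 1.0)
        B[v] = np.where(onpath, counts / denom, 0.0).sum() / 2.0
    return B, SC


def _efficiency_from_dist(D: np.ndarray) -> float:
    """E = mean of 1/d over ordered pairs, 1/d = 0 when unreachable."""
    n = D.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _eigenvector_centrality(net: Network) -> np.ndarray:
    """Leading eigenvector of the largest component's adjacency matrix,
    non-negative, unit Euclidean norm; nodes outside the component get 0."""
    nodes = net.node_ids
    comps = sorted(
        (sorted(c) for c in nx.connected_components(net.graph)),
        key=lambda c: (-len(c), c),
    )
    giant = comps[0]
    a = nx.to_numpy_array(net.graph, nodelist=giant)
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, -1])
    lead /= np.linalg.norm(lead)
    ec = np.zeros(len(nodes))
    pos = {u: i for i, u in enumerate(nodes)}
    for u, val in zip(giant, lead):
        ec[pos[u]] = val
    return ec


def _star_centralization_denominators(n: int) -> dict[str, float]:
    """Maximum centralization sums attained by the n-node star, computed
    numerically on the star itself."""
    star = Network(nx.star_graph(n - 1))
    _, adj = _adjacency(star)
    D, Sg = _all_pairs(adj)
    B, SC = _betweenness_stress(D, Sg)
    EC = _eigenvector_centrality(star)
    return {
        "CB": float((B.max() - B).sum()),
        "CS": float((SC.max() - SC).sum()),
        "CE": float((EC.max() - EC).sum()),
    }


def node_topology(net: Network) -> pd.DataFrame:
    """All six per-node indices, as a DataFrame indexed by node id."""
    nodes, adj = _adjacency(net)
    n = len(nodes)
    D, Sg = _all_pairs(adj)
    B, SC = _betweenness_stress(D, Sg)
    k = np.array([len(a) for a in adj], dtype=float)
    cc_map = nx.clustering(net.graph)
    cc = np.array([cc_map[u] for u in nodes])
    ec = _eigenvector_centrality(net)

    eff = _efficiency_from_dist(D)
    vuln = np.zeros(n)
    if eff > 0 and n > 1:
        for i in range(n):
            old = [j for j in range(n) if j != i]
            remap = {o: x for x, o in enumerate(old)}
            sub = [[remap[w] for w in adj[o] if w != i] for o in old]
            Di, _ = _all_pairs(sub)
            vuln[i] = (eff - _efficiency_from_dist(Di)) / eff

    return pd.DataFrame(
        {"k": k, "SC": SC, "B": B, "EC": ec, "CC": cc, "V": vuln}, index=nodes
    )


def global_topology(net: Network) -> GlobalTopology:
    """All whole-network indices plus the power-law and scaling-law fits."""
    nodes, adj = _adjacency(net)
    n, L = net.n, net.L
    D, Sg = _all_pairs(adj)
    B, SC = _betweenness_stress(D, Sg)
    k = np.array([len(a) for a in adj], dtype=float)
    ec = _eigenvector_centrality(net)
    cc_map = nx.clustering(net.graph)
    cc = np.array([cc_map[u] for u in nodes])

    finite = np.isfinite(D) & ~np.eye(n, dtype=bool)
    n_reach = int(finite.sum())
    gd = float(D[finite].sum() / n_reach) if n_reach else math.inf
    eff = _efficiency_from_dist(D)
    hd = 1.0 / eff if eff > 0 else math.inf
    w_unreach = int((~np.isfinite(D)).sum() // 2)
    con = 1.0 - w_unreach / (n * (n - 1) / 2.0)

    if n > 2:
        cd = float((k.max() - k).sum() / ((n - 1) * (n - 2)))
        denoms = _star_centralization_denominators(n)
        cb = float((B.max() - B).sum() / denoms["CB"]) if denoms["CB"] > 0 else 0.0
        cs = float((SC.max() - SC).sum() / denoms["CS"]) if denoms["CS"] > 0 else 0.0
        ce = float((ec.max() - ec).sum() / denoms["CE"]) if denoms["CE"] > 0 else 0.0
    else:
        cd = cb = cs = ce = 0.0

    return GlobalTopology(
        n=n,
        L=L,
        avg_k=2.0 * L / n,
        gd=gd,
        efficiency=eff,
        hd=hd,
        cd=cd,
        cb=cb,
        cs=cs,
        ce=ce,
        density=2.0 * L / (n * (n - 1)) if n > 1 else 0.0,
        avg_cc=float(cc.mean()),
        transitivity=float(nx.transitivity(net.graph)),
        connectedness=con,
        unreachable_pairs=w_unreach,
        power_law=fit_power_law(net),
        scaling_law=fit_scaling_law(net),
    )


def fit_power_law(net: Network) -> FitResult:
    """OLS of log P(k) vs log k, P(k) = number of degree-k nodes."""
    counts = Counter(d for _, d in net.graph.degree())
    ks = sorted(kk for kk, c in counts.items() if c > 0 and kk > 0)
    if len(ks) < 3:
        return FitResult(math.nan, math.nan, False, len(ks))
    x = np.log([float(kk) for kk in ks])
    y = np.log([float(counts[kk]) for kk in ks])
    fit = stats.linregress(x, y)
    return FitResult(-float(fit.slope), float(fit.rvalue) ** 2, True, len(ks))


def fit_scaling_law(net: Network) -> FitResult:
    """OLS of log C(k) vs log k, C(k) = mean clustering coefficient of
    degree-k nodes; nodes with k <= 1 are excluded."""
    cc = nx.clustering(net.graph)
    groups: dict[int, list[float]] = {}
    for u, d in net.graph.degree():
        if d >= 2:
            groups.setdefault(d, []).append(cc[u])
    pts = [(kk, float(np.mean(v))) for kk, v in sorted(groups.items())]
    pts = [(kk, c) for kk, c in pts if c > 0]
    if len(pts) < 3:
        return FitResult(math.nan, math.nan, False, len(pts))
    x = np.log([kk for kk, _ in pts])
    y = np.log([c for _, c in pts])
    fit = stats.linregress(x, y)
    return FitResult(-float(fit.slope), float(fit.rvalue) ** 2, True, len(pts))


def _node_set_at_threshold(values: np.ndarray, otu_ids: list[str], s_t: float) -> set[str]:
    """Nodes with at least one |r| >= s_t, from raw (unstandardized) rows."""
    means = values.mean(axis=1)
    sds = values.std(axis=1)
    keep = np.flatnonzero(sds > 0)
    if keep.size < 2:
        return set()
    x = (values[keep] - means[keep, None]) / sds[keep, None]
    r = np.abs(x @ x.T) / values.shape[1]
    np.fill_diagonal(r, 0.0)
    linked = np.flatnonzero((r >= s_t).any(axis=1))
    return {otu_ids[keep[i]] for i in linked}


def noise_robustness(
    table: AbundanceTable,
    s_t: float,
    levels: list[float],
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Node-set stability under additive Gaussian noise.

    For each noise level ``l`` the table is perturbed with i.i.d. Gaussian
    noise of sd = l x (grand mean of the table), re-standardized and
    re-thresholded at the *same* similarity cutoff; reported per level
    (averaged over ``reps`` seeded replicates):

    * ``preserved`` - fraction of original network nodes still present;
    * ``precision`` - fraction of perturbed-network nodes that belong to the
      original network.
    """
    if table.stage not in ("relative", "filtered"):
        raise ValueError("noise robustness expects a relative-abundance table")
    rng = np.random.default_rng(seed)
    grand = float(table.values.mean())
    original = _node_set_at_threshold(table.values, table.otu_ids, s_t)
    if not original:
        raise ValueError(f"empty network at threshold {s_t}")
    rows = []
    for level in levels:
        pres, prec = [], []
        for _ in range(reps):
            if level == 0:
                noisy = table.values
            else:
                noisy = table.values + rng.normal(0.0, level * grand, table.values.shape)
            nodes = _node_set_at_threshold(noisy, table.otu_ids, s_t)
            inter = len(original & nodes)
            pres.append(inter / len(original))
            prec.append(inter / len(nodes) if nodes else 0.0)
        rows.append((level, float(np.mean(pres)), float(np.mean(prec))))
    return pd.DataFrame(rows, columns=["level", "preserved", "precision"]).set_index("level")
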