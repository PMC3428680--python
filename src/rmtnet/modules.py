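"""Module detection by modularity optimization and Zi-Pi node roles.

Modularity of a partition into N_M modules:

    M = sum_b [ l_b / L - (K_b / (2L))^2 ]

with l_b the number of within-module links, K_b the summed degree of module
b's members and L the total link count; M lies in [-1, 1].

Node roles come from the within-module degree z-score

    z_i = (k_ib - mean_b) / sd_b        (z_i = 0 when sd_b = 0)

and the participation coefficient (among-module connectivity)

    P_i = 1 - sum_c (k_ic / k_i)^2.

Roles: peripheral (z <= 2.5, P <= 0.62), connector (z <= 2.5, P > 0.62),
module hub (z > 2.5, P <= 0.62), network hub (z > 2.5, P > 0.62).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import Network

__all__ = [
    "ModulePartition",
    "Z_THRESHOLD",
    "P_THRESHOLD",
    "modularity_score",
    "detect_modules",
    "node_roles",
    "role_category",
    "rand_index",
]

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

METHODS = ("fast_greedy", "leading_eigenvector", "short_random_walks", "simulated_annealing")


@dataclass
class ModulePartition:
    """Node -> module assignment with per-module tallies and modularity."""

    assignment: dict[str, int]
    n_modules: int
    within_links: dict[int, int]
    degree_sums: dict[int, int]
    modularity: float
    method: str

    def members(self, b: int) -> list[str]:
        return sorted(u for u, lbl in self.assignment.items() if lbl == b)

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lbl in self.assignment.values():
            sizes[lbl] = sizes.get(lbl, 0) + 1
        return sizes

    def modules_of_size(self, min_size: int) -> list[int]:
        return sorted(b for b, s in self.module_sizes().items() if s >= min_size)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.assignment.items())
        return pd.DataFrame(items, columns=["node", "module"]).set_index("node")


def _tallies(net: Network, assignment: dict[str, int]) -> tuple[dict[int, int], dict[int, int]]:
    within: dict[int, int] = {}
    ksum: dict[int, int] = {}
    for u, lbl in assignment.items():
        ksum[lbl] = ksum.get(lbl, 0) + net.graph.degree(u)
        within.setdefault(lbl, 0)
    for u, v in net.graph.edges():
        if assignment[u] == assignment[v]:
            within[assignment[u]] += 1
    return within, ksum


def modularity_score(net: Network, assignment: dict[str, int]) -> float:
    """Newman modularity of an explicit node -> module assignment."""
    missing = [u for u in net.graph.nodes() if u not in assignment]
    if missing:
        raise ValueError(f"nodes without a module assignment: {sorted(missing)[:5]}")
    L = net.L
    within, ksum = _tallies(net, assignment)
    return float(
        sum(within[b] / L - (ksum[b] / (2.0 * L)) ** 2 for b in within)
    )


def _relabel(net: Network, groups: list[set[str]], method: str) -> ModulePartition:
    """Canonical labels 1..N_M: decreasing size, ties by smallest member id."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    assignment = {u: b + 1 for b, g in enumerate(ordered) for u in g}
    within, ksum = _tallies(net, assignment)
    return ModulePartition(
        assignment=assignment,
        n_modules=len(ordered),
        within_links=within,
        degree_sums=ksum,
        modularity=modularity_score(net, assignment),
        method=method,
    )


def _fast_greedy(net: Network) -> list[set[str]]:
    """Greedy agglomeration: start from singletons, repeatedly merge the
    module pair with the largest modularity gain, stop when no merge
    increases M.  Ties broken by lexicographically smallest module labels
    (labels = smallest member id), which makes the result deterministic."""
    L = float(net.L)
    nodes = net.node_ids
    # module label = smallest member id; keeps tie-breaking well-defined
    members: dict[str, set[str]] = {u: {u} for u in nodes}
    ksum: dict[str, float] = {u: float(net.graph.degree(u)) for u in nodes}
    # between-module edge counts, keyed by sorted label pair
    between: dict[tuple[str, str], float] = {}
    for u, v in net.graph.edges():
        key = (min(u, v), max(u, v))
        between[key] = between.get(key, 0.0) + 1.0

    while between:
        best_gain = 0.0
        best_key = None
        # lexicographic iteration + strict improvement = deterministic
        # smallest-label tie-break
        for key in sorted(between):
            a, b = key
            gain = between[key] / L - ksum[a] * ksum[b] / (2.0 * L * L)
            if gain > best_gain + 1e-15:
                best_gain = gain
                best_key = key
        if best_key is None:
            break
        a, b = best_key  # a < b: merge b into a
        members[a] |= members.pop(b)
        ksum[a] += ksum.pop(b)
        merged: dict[tuple[str, str], float] = {}
        for (x, y), e in between.items():
            if (x, y) == (a, b):
                continue
            x2 = a if x == b else x
            y2 = a if y == b else y
            if x2 == y2:
                continue
            key = (min(x2, y2), max(x2, y2))
            merged[key] = merged.get(key, 0.0) + e
        between = merged
    return list(members.values())


def _igraph_partition(net: Network, method: str, seed: int | None) -> list[set[str]]:
    import igraph as ig

    nodes = net.node_ids
    index = {u: i for i, u in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges()]
    g = ig.Graph(n=len(nodes), edges=edges)
    if method == "leading_eigenvector":
        clustering = g.community_leading_eigenvector()
    else:  # short_random_walks
        clustering = g.community_walktrap(steps=4).as_clustering()
    groups: dict[int, set[str]] = {}
    for i, lbl in enumerate(clustering.membership):
        groups.setdefault(lbl, set()).add(nodes[i])
    return list(groups.values())


def _simulated_annealing(net: Network, seed: int | None) -> list[set[str]]:
    """Direct maximization of M by single-node moves with geometric cooling
    (factor 0.995), initialized from the fast-greedy partition."""
    rng = np.random.default_rng(seed)
    start = _fast_greedy(net)
    nodes = net.node_ids
    label = {u: i for i, g in enumerate(start) for u in g}
    n_labels = len(start) + 1  # one spare empty label allows splitting
    L = float(net.L)
    deg = {u: float(net.graph.degree(u)) for u in nodes}
    ksum = np.zeros(n_labels)
    for u in nodes:
        ksum[label[u]] += deg[u]

    def gain_of_move(u: str, new: int) -> float:
        old = label[u]
        if new == old:
            return 0.0
        e_old = sum(1 for w in net.graph[u] if label[w] == old)
        e_new = sum(1 for w in net.graph[u] if label[w] == new)
        d = deg[u]
        return (e_new - e_old) / L - d * (ksum[new] - (ksum[old] - d)) / (2.0 * L * L)

    # set the initial temperature so that a typical uphill move is accepted
    # with probability ~0.5
    sample = [abs(gain_of_move(u, int(rng.integers(n_labels)))) for u in nodes[: min(len(nodes), 50)]]
    scale = np.median([s for s in sample if s > 0] or [1e-3])
    temp = scale / np.log(2.0)
    best_label = dict(label)
    best_m = modularity_score(net, {u: int(l) for u, l in label.items()})
    current_m = best_m
    for _ in range(200 * len(nodes)):
        u = nodes[int(rng.integers(len(nodes)))]
        new = int(rng.integers(n_labels))
        dm = gain_of_move(u, new)
        if dm >= 0 or rng.random() < np.exp(dm / max(temp, 1e-12)):
            old = label[u]
            ksum[old] -= deg[u]
            ksum[new] += deg[u]
            label[u] = new
            current_m += dm
            if current_m > best_m + 1e-12:
                best_m = current_m
                best_label = dict(label)
        temp *= 0.995
    groups: dict[int, set[str]] = {}
    for u, lbl in best_label.items():
        groups.setdefault(lbl, set()).add(u)
    return list(groups.values())


def detect_modules(
    net: Network, method: str = "fast_greedy", seed: int | None = None
) -> ModulePartition:
    """Partition the network into modules by modularity optimization.

    ``fast_greedy`` (default) is deterministic; ``leading_eigenvector`` and
    ``short_random_walks`` are delegated to igraph; ``simulated_annealing``
    directly maximizes M with a seeded annealing schedule.
    """
    if net.n == 0:
        raise ValueError("empty network")
    if method == "fast_greedy":
        groups = _fast_greedy(net)
    elif method in ("leading_eigenvector", "short_random_walks"):
        groups = _igraph_partition(net, method, seed)
    elif method == "simulated_annealing":
        groups = _simulated_annealing(net, seed)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return _relabel(net, groups, method)


def role_category(z: float, p: float) -> str:
    """Topological role from the (z, P) plane.

    Peripheral (z <= 2.5, P <= 0.62): few links, almost all within the own
    module; connector (z <= 2.5, P > 0.62): links several modules; module
    hub (z > 2.5, P <= 0.62): highly connected within its module; network
    hub (z > 2.5, P > 0.62): both.
    """
    if z <= Z_THRESHOLD:
        return "peripheral" if p <= P_THRESHOLD else "connector"
    return "module_hub" if p <= P_THRESHOLD else "network_hub"


def node_roles(net: Network, partition: ModulePartition) -> pd.DataFrame:
    """Zi-Pi role table: z, P, per-module link split and role category.

    Within-module degree statistics use the population sd over module
    members; modules whose members all have the same within-module degree
    give z = 0.
    """
    assignment = partition.assignment
    nodes = net.node_ids
    labels = sorted(set(assignment.values()))
    kib: dict[str, int] = {}
    kic: dict[str, dict[int, int]] = {}
    for u in nodes:
        split: dict[int, int] = {}
        for w in net.graph[u]:
            c = assignment[w]
            split[c] = split.get(c, 0) + 1
        kic[u] = split
        kib[u] = split.get(assignment[u], 0)

    stats_by_module: dict[int, tuple[float, float]] = {}
    for b in labels:
        vals = np.array([kib[u] for u in nodes if assignment[u] == b], dtype=float)
        stats_by_module[b] = (float(vals.mean()), float(vals.std()))

    rows = []
    for u in nodes:
        b = assignment[u]
        mean_b, sd_b = stats_by_module[b]
        z = (kib[u] - mean_b) / sd_b if sd_b > 0 else 0.0
        k = net.graph.degree(u)
        p = 1.0 - sum((c / k) ** 2 for c in kic[u].values())
        rows.append((u, b, k, kib[u], z, p, role_category(z, p)))
    return pd.DataFrame(
        rows, columns=["node", "module", "k", "k_within", "z", "P", "role"]
    ).set_index("node")


def rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Rand index between two labelings over their shared keys."""
    keys = sorted(set(labels_a) & set(labels_b))
    if len(keys) < 2:
        raise ValueError("need at least 2 shared items")
    agree = 0
    total = 0
    for i, u in enumerate(keys):
        for v in keys[i + 1 :]:
            same_a = labels_a[u] == labels_a[v]
            same_b = labels_b[u] == labels_b[v]
            agree += same_a == same_b
            total += 1
    return agree / total
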