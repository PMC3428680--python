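"""Shared test utilities: graph builders and independent brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx

from rmtnet.topology import Network


def net_from_edges(edges, sign=1, similarity=0.9) -> Network:
    """Build a Network from a plain edge list with default attributes."""
    g = nx.Graph()
    for e in edges:
        if len(e) == 2:
            u, v = e
            g.add_edge(str(u), str(v), similarity=similarity, sign=sign)
        else:
            u, v, attrs = e
            g.add_edge(str(u), str(v), **attrs)
    return Network(g)


def net_from_graph(g: nx.Graph) -> Network:
    h = nx.Graph()
    for u, v in g.edges():
        h.add_edge(str(u), str(v), similarity=0.9, sign=1)
    return Network(h)


def random_net(n: int, p: float, seed: int) -> Network | None:
    """Seeded G(n, p) with isolated nodes dropped; None if edgeless."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        return None
    return net_from_graph(g)


def brute_force_paths(net: Network):
    """Exhaustive shortest-path enumeration oracle.

    Enumerates every shortest path of every unordered node pair with
    networkx's all_shortest_paths (BFS DAG traversal) and accumulates
    betweenness, stress, geodesic distance and efficiency from the explicit
    path lists — an independent route from the implementation's
    path-counting algebra.
    """
    g = net.graph
    nodes = net.node_ids
    B = {u: 0.0 for u in nodes}
    SC = {u: 0 for u in nodes}
    dist_sum = 0
    reachable_pairs = 0
    inv_sum = 0.0
    n = len(nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        d = len(paths[0]) - 1
        dist_sum += d
        reachable_pairs += 1
        inv_sum += 1.0 / d
        total = len(paths)
        through = {}
        for path in paths:
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
        for v, c in through.items():
            SC[v] += c
            B[v] += c / total
    gd = dist_sum / reachable_pairs if reachable_pairs else float("inf")
    eff = 2.0 * inv_sum / (n * (n - 1)) if n > 1 else 0.0
    return B, SC, gd, eff


def brute_force_clustering(net: Network):
    """CC_i = 2 l_i / (k_i (k_i - 1)) by direct neighbour-pair counting."""
    g = net.graph
    out = {}
    for u in net.node_ids:
        nbrs = list(g[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        out[u] = 2.0 * links / (k * (k - 1))
    return out


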