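"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
combinatorics, hand-rolled regression — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction
from itertools import combinations


# ---------------------------------------------------------------------------
# graph oracles (adjacency given as dict node -> set of neighbours)


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_path_metrics(adj: dict) -> tuple[float, int]:
    """Mean and max shortest-path distance over connected unordered pairs."""
    nodes = sorted(adj)
    dists = []
    for i, s in enumerate(nodes):
        d = bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            if t in d:
                dists.append(d[t])
    if not dists:
        return 0.0, 0
    return sum(dists) / len(dists), max(dists)


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s-t path, by backtracking over a BFS distance map."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(node, suffix):
        if node == s:
            paths.append([s] + suffix)
            return
        for p in adj[node]:
            if p in dist and dist[p] == dist[node] - 1:
                back(p, [node] + suffix)

    back(t, [])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness by full shortest-path enumeration.

    Sum over unordered pairs s != t of (shortest s-t paths through v) /
    (all shortest s-t paths), matching the undirected unnormalized
    convention.
    """
    nodes = sorted(adj)
    bw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bw[v] += through / len(paths)
    return bw


def brute_clustering(adj: dict) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    total = 0.0
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        total += 2 * links / (k * (k - 1))
    return total / len(adj)


# ---------------------------------------------------------------------------
# regression / statistics oracles


def loglog_regression(ks, ps) -> tuple[float, float, float]:
    """OLS of log10 p on log10 k by the normal equations.

    Returns (slope, intercept, r_squared).
    """
    xs = [math.log10(k) for k in ks]
    ys = [math.log10(p) for p in ps]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((y - (slope * x + intercept)) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - my) ** 2 for y in ys)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n), as a Fraction."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return total


def bh_step_up(ps: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, hand-rolled step-up."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, ps[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def pooled_t_two_sided(x: list[float], y: list[float]) -> tuple[float, float]:
    """Classical pooled two-sample t and two-sided p from the t tail."""
    from scipy.special import stdtr

    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((a - m1) ** 2 for a in x) / (n1 - 1)
    v2 = sum((a - m2) ** 2 for a in y) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m2 - m1) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, p


# ---------------------------------------------------------------------------
# clustering oracle


def brute_min_two_partition_inertia(X) -> float:
    """Exhaustive minimum within-cluster SSQ over all 2-partitions of rows."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = math.inf
    for mask in range(1, 2 ** (n - 1)):  # fix row 0 in cluster 0: halves the space
        members = [(mask >> i) & 1 for i in range(n - 1)]
        labels = [0] + members
        inertia = 0.0
        for c in (0, 1):
            rows = X[[i for i in range(n) if labels[i] == c]]
            if len(rows) == 0:
                continue
            inertia += float(((rows - rows.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


# ---------------------------------------------------------------------------
# random-graph helper (numpy only, independent of networkx generators)


def random_connected_adjacency(rng, n: int, extra_edge_prob: float = 0.3) -> dict:
    """Random connected graph: a random spanning tree plus random extras."""
    nodes = [f"n{i}" for i in range(n)]
    adj = {v: set() for v in nodes}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        adj[nodes[i]].add(nodes[j])
        adj[nodes[j]].add(nodes[i])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < extra_edge_prob:
                adj[nodes[i]].add(nodes[j])
                adj[nodes[j]].add(nodes[i])
    return adj


def adjacency_to_network(adj: dict):
    from hubnet import InteractionNetwork

    edges = set()
    for u, nbrs in adj.items():
        for v in nbrs:
            edges.add((min(u, v), max(u, v)))
    return InteractionNetwork.from_edges(
        [(a, b, 1.0) for a, b in sorted(edges)], nodes=sorted(adj)
    )
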