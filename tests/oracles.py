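"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive and written against raw edge
lists, not against the package's own code paths: Floyd-Warshall for
distances, closed-form sums for OLS, exhaustive path enumeration for
betweenness, a truncated power series for the matrix exponential.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

INF = float("inf")


def fw_distances(nodes: list, edges: list[tuple]) -> dict:
    """All-pairs shortest paths by pure-Python Floyd-Warshall."""
    d = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for u, v in edges:
        d[(u, v)] = d[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = d[(i, k)] + d[(k, j)]
                if alt < d[(i, j)]:
                    d[(i, j)] = alt
    return d


def ols_slope(xs, ys) -> float:
    """Closed-form least-squares slope: Sxy / Sxx."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return sxy / sxx


def _profile(nodes, edges, v):
    d = fw_distances(nodes, edges)
    return {u: int(d[(v, u)]) for u in nodes if d[(v, u)] < INF}


def lfd_oracle(nodes, edges, v) -> float:
    prof = _profile(nodes, edges, v)
    ecc = max(prof.values())
    if ecc < 2:
        return 0.0
    rs = range(1, ecc + 1)
    counts = [sum(1 for d in prof.values() if d <= r) for r in rs]
    return ols_slope([math.log(r) for r in rs], [math.log(c) for c in counts])


def lffd_oracle(nodes, edges, v) -> float:
    prof = _profile(nodes, edges, v)
    ecc = max(prof.values())
    if ecc < 2:
        return 0.0
    rs = range(1, ecc + 1)
    vals = []
    for r in rs:
        mem = [math.exp(-d * d / (2 * r * r)) for d in prof.values() if d <= r]
        vals.append(sum(mem) / len(mem))
    return ols_slope([math.log(r) for r in rs], [math.log(x) for x in vals])


def _all_paths(adj, s, t, max_len):
    """All simple paths from s to t of length <= max_len (DFS)."""
    out = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            out.append(path)
            continue
        if len(path) > max_len:
            continue
        for w in adj[node]:
            if w not in path:
                stack.append((w, path + [w]))
    return out


def betweenness_oracle(nodes, edges, v) -> float:
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    d = fw_distances(nodes, edges)
    total = 0.0
    for s, t in combinations(nodes, 2):
        if s == v or t == v or d[(s, t)] == INF:
            continue
        shortest = [p for p in _all_paths(adj, s, t, d[(s, t)])
                    if len(p) - 1 == d[(s, t)]]
        through = sum(1 for p in shortest if v in p)
        if shortest:
            total += through / len(shortest)
    return total


def closeness_oracle(nodes, edges, v) -> float:
    prof = _profile(nodes, edges, v)
    tot = sum(prof.values())
    return (len(prof) - 1) / tot if tot else 0.0


def clustering_oracle(nodes, edges, v) -> float:
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nbrs = adj[v]
    k = len(nbrs)
    if k < 2:
        return 0.0
    e = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
    return 2.0 * e / (k * (k - 1))


def subgraph_centrality_oracle(nodes, edges) -> dict:
    """diag(exp(A)) by a truncated Taylor series on the dense adjacency."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b in edges:
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
    term = np.eye(n)
    total = np.eye(n)
    for k in range(1, 60):
        term = term @ A / k
        total += term
    return {u: float(total[idx[u], idx[u]]) for u in nodes}


def lac_oracle(nodes, edges, v) -> float:
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nbrs = adj[v]
    if not nbrs:
        return 0.0
    within = {w: len(adj[w] & nbrs) for w in nbrs}
    return sum(within.values()) / len(nbrs)


def lid_oracle(nodes, edges, v) -> float:
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    nbrs = sorted(adj[v])
    return float(sum(1 for a, b in combinations(nbrs, 2) if b in adj[a]))
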