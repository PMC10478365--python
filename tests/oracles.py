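"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (BFS path counting,
combinatorial enumeration, the textbook Welch and BH formulas) and shares no
code path with the package under test.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def bfs_paths(adj: dict, source):
    """Distances and shortest-path counts from `source` by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges) -> dict:
    """Normalized betweenness by exhaustive pair/path counting.

    The count of shortest s-t paths through v is sigma(s,v) * sigma(v,t)
    whenever dist(s,v) + dist(v,t) == dist(s,t); disconnected pairs
    contribute nothing.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    all_dist, all_sigma = {}, {}
    for v in nodes:
        all_dist[v], all_sigma[v] = bfs_paths(adj, v)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if t not in all_sigma[s] or all_sigma[s][t] == 0:
            continue
        d_st = all_dist[s][t]
        total = all_sigma[s][t]
        for v in nodes:
            if v in (s, t):
                continue
            if v in all_dist[s] and t in all_dist[v]:
                if all_dist[s][v] + all_dist[v][t] == d_st:
                    bc[v] += all_sigma[s][v] * all_sigma[v][t] / total
    n = len(nodes)
    scale = (n - 1) * (n - 2) / 2.0
    if scale > 0:
        for v in nodes:
            bc[v] /= scale
    return bc


def brute_clustering(nodes, edges) -> dict:
    """cc = (connected neighbour pairs) / C(k, 2), zero below degree 2."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    cc = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            cc[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        cc[v] = 2.0 * links / (k * (k - 1))
    return cc


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for the hypergeometric by direct enumeration with comb()."""
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_step_up(pvalues) -> list:
    """Benjamini-Hochberg step-up from the definition: sort, multiply by
    m/rank, enforce monotonicity from the largest down, clip at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, pvalues[i] * m / (pos + 1))
        adjusted[i] = min(running, 1.0)
    return adjusted


def welch_reference(x, y) -> tuple:
    """(t, df) from the Welch formulas written out longhand."""
    nx_, ny = len(x), len(y)
    mx = sum(x) / nx_
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx_ - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx_ + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
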