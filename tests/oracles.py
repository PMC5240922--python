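"""Independent reference implementations used only to check the package.

These deliberately use different algorithms and data structures than the
library (dict counting instead of bincount, heapq Dijkstra instead of
Floyd–Warshall, exhaustive path enumeration instead of counting DPs) so
agreement is meaningful.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict

import numpy as np

GAP = 20


def mi_entropy_oracle(matrix: np.ndarray, weights: np.ndarray, i: int, j: int) -> float:
    """Plug-in MI via H(i) + H(j) - H(i,j) with dict-based weighted counts,
    pairwise-complete over gaps, no pseudocount."""
    ci: dict = defaultdict(float)
    cj: dict = defaultdict(float)
    cij: dict = defaultdict(float)
    total = 0.0
    for row, w in zip(matrix, weights):
        a, b = int(row[i]), int(row[j])
        if a == GAP or b == GAP:
            continue
        ci[a] += w
        cj[b] += w
        cij[(a, b)] += w
        total += w
    if total < 2:
        return 0.0

    def entropy(counts) -> float:
        return -sum((c / total) * math.log(c / total) for c in counts.values() if c > 0)

    return entropy(ci) + entropy(cj) - entropy(cij)


def apc_oracle(mi: np.ndarray) -> np.ndarray:
    """Average product correction with explicit loops."""
    n = mi.shape[0]
    row = [sum(mi[i, j] for j in range(n) if j != i) / (n - 1) for i in range(n)]
    overall = sum(row) / n
    out = np.zeros_like(mi)
    for i in range(n):
        for j in range(n):
            if i != j and overall != 0:
                out[i, j] = mi[i, j] - (row[i] / overall) * row[j]
            elif i != j:
                out[i, j] = mi[i, j]
    return out


def dijkstra_oracle(n: int, edges: dict[tuple[int, int], float], src: int) -> np.ndarray:
    """Textbook heapq Dijkstra on an undirected edge dict."""
    adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    heap = [(0.0, src)]
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        for v, w in adj[u]:
            if d + w < dist[v]:
                dist[v] = d + w
                heapq.heappush(heap, (d + w, v))
    return dist


def enumerate_shortest_paths(
    n: int, edges: dict[tuple[int, int], float], s: int, t: int
) -> list[tuple[int, ...]]:
    """All shortest s→t paths by DFS over the shortest-path DAG."""
    ds = dijkstra_oracle(n, edges, s)
    dt = dijkstra_oracle(n, edges, t)
    if not np.isfinite(ds[t]):
        return []
    total = ds[t]
    adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    out: list[tuple[int, ...]] = []

    def dfs(u: int, path: list[int]) -> None:
        if u == t:
            out.append(tuple(path))
            return
        for v, w in adj[u]:
            if abs(ds[u] + w - ds[v]) <= 1e-12 and abs(ds[v] + dt[v] - total) <= 1e-12:
                dfs(v, path + [v])

    dfs(s, [s])
    return out


def betweenness_enumeration_oracle(
    n: int, edges: dict[tuple[int, int], float]
) -> np.ndarray:
    """Raw betweenness by enumerating every shortest path of every pair
    and crediting interior nodes fractionally."""
    raw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(n, edges, s, t)
            if not paths:
                continue
            for path in paths:
                for node in path[1:-1]:
                    raw[node] += 1.0 / len(paths)
    return raw


def random_weighted_graph(
    rng: np.random.Generator, n: int, p: float = 0.35
) -> dict[tuple[int, int], float]:
    """Connected random graph with weights quantized to multiples of 0.25
    so co-optimal path identification is exact in floating point."""
    while True:
        edges: dict[tuple[int, int], float] = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges[(i, j)] = 0.25 * int(rng.integers(1, 9))
        if not edges:
            continue
        d = dijkstra_oracle(n, edges, 0)
        if np.all(np.isfinite(d)):
            return edges
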