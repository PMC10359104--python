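"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_degree(adj: np.ndarray) -> list[int]:
    n = len(adj)
    return [sum(int(adj[i][j]) for j in range(n)) for i in range(n)]


def brute_mean_distance(adj: np.ndarray) -> float | None:
    """BFS shortest paths averaged over reachable unordered pairs."""
    n = len(adj)
    total, count = 0, 0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u][v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in range(s + 1, n):
            if t in dist:
                total += dist[t]
                count += 1
    return total / count if count else None


def brute_transitivity(adj: np.ndarray) -> float:
    """3 x triangles / connected triples, by explicit enumeration."""
    n = len(adj)
    triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if adj[i][j] and adj[j][k] and adj[i][k]:
                    triangles += 1
    triples = 0
    for i in range(n):
        d = sum(int(adj[i][j]) for j in range(n))
        triples += d * (d - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def brute_modularity(adj: np.ndarray, membership) -> float | None:
    """Newman-Girvan Q by the full double sum over node pairs."""
    n = len(adj)
    k = [sum(int(adj[i][j]) for j in range(n)) for i in range(n)]
    two_m = sum(k)
    if two_m == 0:
        return None
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += adj[i][j] - k[i] * k[j] / two_m
    return q / two_m


def brute_holm(p: np.ndarray) -> np.ndarray:
    """Step-down Holm: sort, multiply, running max, cap, unsort."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, p[idx] * (m - rank))
        running = max(running, val)
        adjusted[idx] = running
    return np.array(adjusted)


def brute_alternations(choices: str) -> int:
    count = 0
    for t in range(1, len(choices)):
        if choices[t] != choices[t - 1]:
            count += 1
    return count


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return (adj | adj.T).astype(np.int8)
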