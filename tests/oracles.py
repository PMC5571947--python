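"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and the networkx routines) used
by the package: reachability by repeated edge relaxation, shortest paths
by Floyd–Warshall, second-step citations by adjacency-matrix squaring.
"""

from __future__ import annotations

import math

import numpy as np


def transitive_ancestors(edges, seed) -> set:
    """All nodes with a directed path to ``seed``, by repeated relaxation."""
    reaches = {seed}
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            if v in reaches and u not in reaches:
                reaches.add(u)
                changed = True
    return reaches - {seed}


def depth_oracle(nodes, edges) -> float | None:
    """Mean shortest directed path over connected ordered pairs
    (Floyd–Warshall)."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = [[0.0 if i == j else math.inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[idx[u]][idx[v]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    dists = [
        d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and d[i][j] < math.inf
    ]
    if not dists:
        return None
    return sum(dists) / len(dists)


def width_oracle(nodes, edges) -> float | None:
    """Total length-2 walks / total edges via adjacency-matrix squaring."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    for u, v in edges:
        A[idx[u], idx[v]] = 1
    total_first = int(A.sum())
    if total_first == 0:
        return None
    return int((A @ A).sum()) / total_first


def random_dag(rng: np.random.Generator, max_n: int, p: float = 0.35):
    """Random DAG on ids v0..v{n-1}; later nodes may cite earlier ones."""
    n = int(rng.integers(2, max_n + 1))
    ids = [f"v{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i):
            if rng.random() < p:
                edges.add((ids[i], ids[j]))
    return ids, edges


def random_digraph(rng: np.random.Generator, max_n: int, p: float = 0.08):
    """Random digraph (cycles allowed) on ids v0..v{n-1}."""
    n = int(rng.integers(2, max_n + 1))
    ids = [f"v{i}" for i in range(n)]
    edges = {
        (ids[i], ids[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }
    return ids, edges
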