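"""Brute-force reference implementations used as independent oracles.

Deliberately naive: subset enumeration for cliques, explicit path
enumeration for betweenness, BFS tables for distances.  Only suitable for
tiny graphs (<= ~9 nodes) and short p-vectors; the point is independence
from both the package implementation and networkx.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def _adj(nodes: Sequence, edges: Set[Tuple]) -> Dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def brute_degree(nodes, edges):
    adj = _adj(nodes, edges)
    return {v: len(adj[v]) for v in nodes}


def _components(sub_nodes: Set, adj) -> List[Set]:
    remaining, comps = set(sub_nodes), []
    while remaining:
        stack = [next(iter(remaining))]
        comp = set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend((adj[v] & sub_nodes) - comp)
        comps.append(comp)
        remaining -= comp
    return comps


def brute_mnc(nodes, edges):
    adj = _adj(nodes, edges)
    out = {}
    for v in nodes:
        nbrs = adj[v]
        out[v] = max((len(c) for c in _components(nbrs, adj)), default=0)
    return out


def _is_clique(subset, adj) -> bool:
    return all(b in adj[a] for a, b in combinations(subset, 2))


def brute_mcc(nodes, edges):
    """MCC via enumeration of all maximal cliques (subset check)."""
    adj = _adj(nodes, edges)
    node_list = list(nodes)
    cliques = []
    for r in range(1, len(node_list) + 1):
        for subset in combinations(node_list, r):
            if _is_clique(subset, adj):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        for v in c:
            out[v] += factorial(len(c) - 1)
    return out


def _bfs_dist(source, adj):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def brute_harmonic_closeness(nodes, edges):
    adj = _adj(nodes, edges)
    out = {}
    for v in nodes:
        dist = _bfs_dist(v, adj)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def _all_simple_paths(a, b, adj):
    paths = []

    def walk(v, seen, path):
        if v == b:
            paths.append(list(path))
            return
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                path.append(u)
                walk(u, seen, path)
                path.pop()
                seen.remove(u)

    walk(a, {a}, [a])
    return paths


def brute_betweenness(nodes, edges):
    """Betweenness by enumerating all shortest paths per unordered pair."""
    adj = _adj(nodes, edges)
    out = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for a, b in combinations(node_list, 2):
        paths = _all_simple_paths(a, b, adj)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in node_list:
            if v in (a, b):
                continue
            through = sum(1 for p in geodesics if v in p)
            out[v] += through / len(geodesics)
    return out


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH from the definition: adj_i = min_{j: p_j >= p_i} (n p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, n * p[i] / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def brute_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total
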