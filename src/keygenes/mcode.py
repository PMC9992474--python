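"""MCODE molecular-complex detection.

A from-scratch implementation of the classic three-stage MCODE algorithm for
finding densely connected modules in protein-protein interaction networks:

1. *Vertex weighting.*  Each node v is weighted by its core-clustering
   density: take the subgraph induced by v and its neighbors, find its
   highest k-core, and set w(v) = k_max * density(highest k-core).  Nodes
   whose degree falls below ``degree_cutoff`` receive weight 0.

2. *Complex prediction.*  Seeds are processed in descending weight order.
   From each unvisited seed, a breadth-first search includes unvisited
   neighbors whose weight is within ``node_score_cutoff`` of the seed weight
   (w(u) >= w(seed) * (1 - node_score_cutoff)), up to ``max_depth`` hops.
   A node joins at most one complex.

3. *Post-processing.*  Complexes that do not contain a ``k_core``-core are
   discarded.  The haircut option iteratively trims singly connected
   (degree-1) nodes from each complex.  Fluff (re-adding dense neighbors)
   is supported but off by default.

Module score = density * node count, with density = 2E / (N(N-1)); a
complete module of n nodes therefore scores exactly n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import networkx as nx

from .types import Network

__all__ = ["Module", "mcode_vertex_weights", "mcode_cluster"]


@dataclass
class Module:
    """A detected complex: node set, undirected edge count, score, seed node."""

    nodes: Set[str]
    n_edges: int
    score: float
    seed: str

    @property
    def density(self) -> float:
        n = len(self.nodes)
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))


def _graph_density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def _highest_k_core(G: nx.Graph):
    """(k_max, highest k-core subgraph) of G; (0, None) for an empty graph."""
    if G.number_of_nodes() == 0:
        return 0, None
    core_numbers = nx.core_number(G)
    k_max = max(core_numbers.values())
    core_nodes = [v for v, c in core_numbers.items() if c >= k_max]
    return k_max, G.subgraph(core_nodes)


def mcode_vertex_weights(G: nx.Graph, degree_cutoff: int = 2) -> Dict[str, float]:
    """Core-clustering weight w(v) = k_max * density(highest k-core of N[v])."""
    weights: Dict[str, float] = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        neighborhood = G.subgraph([v, *G.neighbors(v)])
        k_max, core = _highest_k_core(neighborhood)
        weights[v] = float(k_max) * _graph_density(core) if core is not None else 0.0
    return weights


def _haircut(H: nx.Graph) -> nx.Graph:
    """Iteratively remove singly connected nodes."""
    H = nx.Graph(H)
    while True:
        leaves = [v for v in H.nodes if H.degree(v) <= 1 and H.number_of_nodes() > 1]
        if not leaves:
            return H
        H.remove_nodes_from(leaves)


def mcode_cluster(
    network: Network,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density_cutoff: float = 0.5,
) -> List[Module]:
    """Run MCODE and return modules sorted by descending score.

    Defaults match the common parameterization: degree cutoff 2, node score
    cutoff 0.2, K-score (k-core filter) 2, max depth 100, haircut on,
    fluff off.  An empty graph yields an empty list.
    """
    G = network.to_networkx()
    if G.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(G, degree_cutoff)

    visited: Set[str] = set()
    complexes: List[tuple] = []  # (seed, node set)
    for seed in sorted(G.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            next_frontier = []
            for v in frontier:
                for u in G.neighbors(v):
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        visited.add(u)
                        next_frontier.append(u)
            frontier = next_frontier
            depth += 1
        complexes.append((seed, members))

    modules: List[Module] = []
    for seed, members in complexes:
        H = G.subgraph(members).copy()
        # k-core filter: the complex must contain a k_core-core at all.
        core_numbers = nx.core_number(H)
        if not core_numbers or max(core_numbers.values()) < k_core:
            continue
        if haircut:
            H = _haircut(H)
        if fluff:
            H = _fluff(G, H, weights, fluff_density_cutoff)
        if H.number_of_nodes() == 0:
            continue
        score = _graph_density(H) * H.number_of_nodes()
        modules.append(Module(set(H.nodes), H.number_of_edges(), score, seed))

    modules.sort(key=lambda m: (-m.score, -len(m.nodes), min(m.nodes)))
    return modules


def _fluff(G: nx.Graph, H: nx.Graph, weights: Dict[str, float], density_cutoff: float) -> nx.Graph:
    """Add neighbors whose neighborhood density exceeds the fluff cutoff."""
    extra = set()
    for v in H.nodes:
        for u in G.neighbors(v):
            if u in H or u in extra:
                continue
            neighborhood = G.subgraph([u, *G.neighbors(u)])
            if _graph_density(neighborhood) > density_cutoff:
                extra.add(u)
    return G.subgraph(set(H.nodes) | extra)
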