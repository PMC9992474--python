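"""Hub-gene centralities and consensus hub selection on PPI networks.

Implements the five node-ranking criteria popularized by the cytoHubba
Cytoscape plug-in — degree, maximum neighborhood component (MNC), maximal
clique centrality (MCC), (harmonic) closeness, and betweenness — plus the
top-k list extraction whose five-way intersection defines the central hub
genes.  All centralities are computed on the unweighted simple graph; edge
confidences only matter at network-construction time.

Conventions for disconnected graphs follow the same tool:

* closeness is harmonic (sum of reciprocal distances, 1/inf = 0), which is
  well-defined off a connected component;
* MCC of a node contained in no clique of size >= 2 is 1 (its singleton
  clique contributes (1-1)! = 1);
* MNC of an isolated node is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .types import Network

__all__ = [
    "CentralityTable",
    "CENTRALITY_METHODS",
    "compute_centralities",
    "top_k_hubs",
    "select_hub_modules",
]

CENTRALITY_METHODS = ("degree", "mnc", "mcc", "closeness", "betweenness")


@dataclass
class CentralityTable:
    """Per-node values of the five hub-ranking criteria."""

    nodes: List[str]
    degree: np.ndarray
    mnc: np.ndarray
    mcc: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray

    def column(self, method: str) -> np.ndarray:
        if method not in CENTRALITY_METHODS:
            raise ValueError(f"unknown centrality method {method!r}; choose from {CENTRALITY_METHODS}")
        return getattr(self, method)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.nodes,
                "degree": self.degree,
                "mnc": self.mnc,
                "mcc": self.mcc,
                "closeness": self.closeness,
                "betweenness": self.betweenness,
            }
        )


def compute_centralities(network: Network) -> CentralityTable:
    """Compute degree, MNC, MCC, harmonic closeness and betweenness per node."""
    G = network.to_networkx()
    nodes = sorted(G.nodes)
    if not nodes:
        return CentralityTable([], *(np.array([]) for _ in range(5)))

    degree = np.array([G.degree(v) for v in nodes], dtype=float)

    # MNC: size of the largest connected component among a node's neighbors.
    mnc = np.zeros(len(nodes))
    for i, v in enumerate(nodes):
        nbrs = list(G.neighbors(v))
        if nbrs:
            sub = G.subgraph(nbrs)
            mnc[i] = max(len(c) for c in nx.connected_components(sub))

    # MCC: sum of (|C|-1)! over maximal cliques C containing the node.
    # networkx's find_cliques reports singleton cliques for isolated nodes,
    # which yields the conventional MCC of 1 there.
    mcc_map: Dict[str, float] = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(G):
        w = float(factorial(len(clique) - 1))
        for v in clique:
            mcc_map[v] += w
    mcc = np.array([mcc_map[v] for v in nodes])

    closeness_map = nx.harmonic_centrality(G)
    closeness = np.array([closeness_map[v] for v in nodes], dtype=float)

    betweenness_map = nx.betweenness_centrality(G, normalized=False)
    betweenness = np.array([betweenness_map[v] for v in nodes], dtype=float)

    return CentralityTable(nodes, degree, mnc, mcc, closeness, betweenness)


def top_k_hubs(table: CentralityTable, method: str, k: int = 30) -> List[str]:
    """Top-k nodes by one centrality, deterministically tie-broken.

    Nodes are sorted descending by the chosen score, ties broken by higher
    degree and then lexicographic id, and the list truncated at k (all nodes
    are returned when the graph is smaller than k).  The ordering is
    prefix-stable: increasing k never reorders earlier entries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    score = table.column(method)
    order = sorted(
        range(len(table.nodes)),
        key=lambda i: (-score[i], -table.degree[i], table.nodes[i]),
    )
    return [table.nodes[i] for i in order[:k]]


def select_hub_modules(modules: Sequence, min_score: float = 5.0, min_nodes: int = 5):
    """Keep modules with score >= min_score and >= min_nodes nodes.

    Returns the kept modules and the union of their node sets (the hub-module
    gene set).  Defaults keep any module scoring at least 5 with at least 5
    nodes; a stricter >=6/>=6 variant can be requested via the arguments.
    """
    kept = [m for m in modules if m.score >= min_score and len(m.nodes) >= min_nodes]
    union: Set[str] = set()
    for m in kept:
        union |= set(m.nodes)
    return kept, union
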