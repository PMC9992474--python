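"""Hypergeometric over-representation analysis on user-supplied gene sets.

A generic one-sided (upper tail) hypergeometric test of a query gene list
against each set of a GMT collection, relative to a finite gene universe.
By default raw p-values are thresholded at 0.05 without multiple-testing
correction, mirroring common web-tool practice; a BH option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Set

import numpy as np
from scipy import stats

from .diffexpr import adjust_bh
from .types import GeneSetCollection, normalize_symbol

__all__ = ["EnrichmentTable", "hypergeometric_enrichment"]


@dataclass
class EnrichmentTable:
    """Significant sets, sorted by ascending p and truncated to top_n."""

    set_ids: List[str]
    descriptions: List[str]
    overlap_counts: List[int]
    overlap_genes: List[List[str]]
    p: np.ndarray

    def __len__(self) -> int:
        return len(self.set_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "set_id": self.set_ids,
                "description": self.descriptions,
                "count": self.overlap_counts,
                "p": self.p,
                "genes": [",".join(g) for g in self.overlap_genes],
            }
        )


def hypergeometric_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    p_cut: float = 0.05,
    top_n: int = 5,
    bh_correct: bool = False,
) -> EnrichmentTable:
    """Upper-tail hypergeometric enrichment p = P(X >= k) for each gene set.

    With N = |universe|, K = |set ∩ universe|, n = |query|, k = |query ∩ set|.
    Query genes outside the universe are dropped with a warning.  Sets with
    p < p_cut are retained, sorted ascending by p (ties: set id) and
    truncated to ``top_n``.
    """
    universe_set = {normalize_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query_set = {normalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("query must be non-empty")
    outside = query_set - universe_set
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
        query_set &= universe_set
        if not query_set:
            raise ValueError("no query genes remain inside the universe")

    N, n = len(universe_set), len(query_set)
    rows = []
    for set_id, (desc, members) in collection.sets.items():
        in_universe = set(members) & universe_set
        K = len(in_universe)
        overlap = sorted(query_set & in_universe)
        k = len(overlap)
        # P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((set_id, desc, k, overlap, min(p, 1.0)))

    pvals = np.array([r[4] for r in rows]) if rows else np.array([])
    if bh_correct and len(pvals):
        pvals = adjust_bh(pvals)
    keep = sorted(
        (i for i in range(len(rows)) if pvals[i] < p_cut),
        key=lambda i: (pvals[i], rows[i][0]),
    )[:top_n]
    return EnrichmentTable(
        [rows[i][0] for i in keep],
        [rows[i][1] for i in keep],
        [rows[i][2] for i in keep],
        [rows[i][3] for i in keep],
        pvals[keep] if len(pvals) else np.array([]),
    )
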