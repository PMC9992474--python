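"""Meta-hub gene frequency analysis and the key-candidate-gene intersection.

The meta-analysis stage counts, for every gene ever reported as a hub gene by
a curated collection of prior studies, the number of distinct studies listing
it.  Genes whose study frequency passes a threshold (default >= 3) are the
"significant meta-hub genes"; intersecting them with the central hub genes
(five-centrality consensus) and the hub-module genes (MCODE) yields the final
key candidate genes.

A transcription of a 52-study hepatocellular-carcinoma hub-gene literature
table ships with the package as ``data/meta_hub_studies.tsv`` (see the
provenance note next to it for its known internal inconsistencies).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Set

from .io import read_meta_study_table
from .svm_filter import intersect_gene_sets
from .types import MetaStudyTable

__all__ = [
    "FrequencyTable",
    "meta_gene_frequencies",
    "significant_meta_hub",
    "key_candidate_genes",
    "load_packaged_meta_table",
]


@dataclass
class FrequencyTable:
    """Distinct-study counts per meta-hub gene; m is the total study count."""

    frequency: Dict[str, int]
    m: int

    def __post_init__(self) -> None:
        bad = {g: f for g, f in self.frequency.items() if not 0 < f <= self.m}
        if bad:
            raise ValueError(f"frequencies outside (0, m={self.m}]: {dict(list(bad.items())[:5])}")

    @property
    def genes(self) -> List[str]:
        return sorted(self.frequency)

    def to_frame(self):
        import pandas as pd

        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame({"gene": [g for g, _ in items], "frequency": [f for _, f in items]})


def meta_gene_frequencies(table: MetaStudyTable) -> FrequencyTable:
    """Count distinct studies per gene (a gene listed twice in a study counts once)."""
    if not table.records:
        raise ValueError("meta-study table is empty")
    freq: Dict[str, int] = {}
    for _, gene in table.records:  # records are already (study, gene)-deduplicated
        freq[gene] = freq.get(gene, 0) + 1
    return FrequencyTable(freq, m=len(table.study_ids))


def significant_meta_hub(freqs: FrequencyTable, min_freq: int = 3, strict: bool = False) -> Set[str]:
    """Genes whose study frequency passes the threshold (>= by default, > if strict)."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    if strict:
        return {g for g, f in freqs.frequency.items() if f > min_freq}
    return {g for g, f in freqs.frequency.items() if f >= min_freq}


def key_candidate_genes(
    central_hubs: Set[str], hub_module_genes: Set[str], significant_meta: Set[str]
) -> Set[str]:
    """Triple intersection of the three gene-identification routes."""
    return intersect_gene_sets([set(central_hubs), set(hub_module_genes), set(significant_meta)])


def load_packaged_meta_table() -> MetaStudyTable:
    """Load the packaged 52-study hepatocellular-carcinoma hub-gene table."""
    path = resources.files("keygenes").joinpath("data/meta_hub_studies.tsv")
    with resources.as_file(path) as p:
        return read_meta_study_table(p)
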