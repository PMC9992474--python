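"""Core in-memory containers shared by every pipeline stage.

All downstream analysis operates on these types; file parsing lives in
:mod:`keygenes.io`.  Gene symbols are normalized (uppercased, stripped) at
construction wherever exact cross-list matching matters, because curated
hub-gene lists from the literature mix symbol cases freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "GeneSetCollection",
    "Network",
    "MetaStudyTable",
    "SurvivalTable",
    "normalize_symbol",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol for exact matching across lists."""
    return symbol.strip().upper()


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of (log2) expression intensities.

    Rows are probes or gene symbols, columns are samples.  Duplicate
    feature ids are permitted (multiple probes per gene before probe
    collapsing); duplicate sample ids are not.
    """

    feature_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids are not allowed")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )

    def row(self, feature_id: str) -> np.ndarray:
        """Values for a single feature; the first match wins on duplicates."""
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not present") from None
        return self.values[i]

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(features)
        index = {f: i for i, f in reversed(list(enumerate(self.feature_ids)))}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        rows = [index[f] for f in wanted]
        return ExpressionMatrix(wanted, list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(samples)
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in wanted]
        return ExpressionMatrix(list(self.feature_ids), wanted, self.values[:, cols])


@dataclass
class PhenotypeTable:
    """Binary case/control labels per sample (case=1, control=0)."""

    sample_ids: List[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary (0=control, 1=case)")

    def aligned_to(self, sample_ids: List[str]) -> np.ndarray:
        """Label vector reordered to a given sample ordering."""
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both case and control samples are required")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set_id -> (description, members)."""

    sets: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: Dict[str, Tuple[str, List[str]]] = {}
        for set_id, (desc, members) in self.sets.items():
            seen: List[str] = []
            for m in members:
                m = normalize_symbol(m)
                if m and m not in seen:
                    seen.append(m)
            if not seen:
                raise ValueError(f"gene set {set_id!r} is empty")
            cleaned[set_id] = (desc, seen)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> List[str]:
        return self.sets[set_id][1]


class Network:
    """Undirected gene network with optional edge confidences in [0, 1].

    Thin wrapper over :class:`networkx.Graph` that enforces the simple-graph
    invariants (no self-loops, no duplicate undirected edges) and records a
    confidence of 1.0 when none is supplied.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[Tuple] = ()):
        self.graph = nx.Graph()
        for n in nodes:
            self.graph.add_node(normalize_symbol(str(n)))
        for e in edges:
            if len(e) == 2:
                a, b = e
                conf = 1.0
            else:
                a, b, conf = e
            self.add_edge(str(a), str(b), float(conf))

    def add_edge(self, a: str, b: str, confidence: float = 1.0) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            return  # self-loops are silently dropped
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self.graph.add_edge(a, b, confidence=confidence)

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str, float]]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, float(data.get("confidence", 1.0))))
        return sorted(out)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        return self.graph


@dataclass
class MetaStudyTable:
    """Long-format (study_id, gene_symbol) records from curated literature.

    Gene symbols are normalized and duplicate (study, gene) pairs collapsed,
    so a gene listed twice within one study contributes a single record.
    """

    records: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        cleaned: List[Tuple[str, str]] = []
        for study, gene in self.records:
            pair = (str(study).strip(), normalize_symbol(str(gene)))
            if pair[1] and pair not in seen:
                seen.add(pair)
                cleaned.append(pair)
        self.records = cleaned

    @property
    def study_ids(self) -> List[str]:
        return sorted({s for s, _ in self.records})

    @property
    def genes(self) -> List[str]:
        return sorted({g for _, g in self.records})

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SurvivalTable:
    """Right-censored follow-up per sample: time (days) and event indicator."""

    sample_ids: List[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("sample_ids, time, event length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event must be 0 (censored) or 1 (death)")

    def subset(self, sample_ids: Iterable[str]) -> "SurvivalTable":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in wanted]
        return SurvivalTable(wanted, self.time[rows], self.event[rows])
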