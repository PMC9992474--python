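"""Readers and writers for every external format the pipeline touches.

The canonical tabular dialect is plain TSV (UTF-8, header line, no quoting),
matching the habits of GEO series-matrix exports.  Gene networks are accepted
as 2/3-column TSV edge lists or SIF.  Gene set collections use the standard
GMT format.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    MetaStudyTable,
    Network,
    PhenotypeTable,
    SurvivalTable,
    normalize_symbol,
)

PathLike = Union[str, Path]

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_probe_map",
    "write_probe_map",
    "read_gene_sets",
    "write_gene_sets",
    "read_network",
    "write_network",
    "read_meta_study_table",
    "write_meta_study_table",
    "read_survival_table",
    "write_survival_table",
]


# ---------------------------------------------------------------- expression

def read_expression_matrix(path: PathLike, transpose_if_needed: bool = False) -> ExpressionMatrix:
    """Read a feature x sample TSV (header = sample ids, first column = feature ids).

    Duplicate feature ids are allowed (multiple probes per gene); duplicate
    sample ids are fatal.  Non-numeric body cells are rejected.  With
    ``transpose_if_needed`` the matrix is transposed when the file stores
    samples as rows (detected only via an explicit ``sample_id`` first header).
    """
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({s for s in header if header.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate sample ids in header: {dupes[:5]}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if transpose_if_needed and str(frame.index.name).strip().lower() in {"sample", "sample_id"}:
        frame = frame.T
        values = values.T
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


# ----------------------------------------------------------------- phenotype

def read_phenotype_table(path: PathLike) -> PhenotypeTable:
    """Read a two-column TSV: sample_id, label (case=1, control=0)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(frame, ("sample_id", "label"), path)
    return PhenotypeTable(list(frame["sample_id"]), frame["label"].to_numpy())


def write_phenotype_table(table: PhenotypeTable, path: PathLike) -> None:
    pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels}).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------- probe map

def read_probe_map(path: PathLike) -> Dict[str, str]:
    """Read a two-column probe -> gene-symbol TSV; symbols are normalized."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ("probe_id", "gene_symbol"), path)
    return {
        str(p): normalize_symbol(g)
        for p, g in zip(frame["probe_id"], frame["gene_symbol"])
        if isinstance(g, str) and g.strip()
    }


def write_probe_map(probe_map: Dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_map), "gene_symbol": list(probe_map.values())}
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets

def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Parse a GMT file: ``set_id TAB description TAB member1 TAB member2 ...``.

    Duplicate members within a line are dropped with a warning; a line with
    fewer than three fields is an error.
    """
    sets = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc, *members = fields
            members = [m for m in members if m.strip()]
            if len({normalize_symbol(m) for m in members}) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {set_id!r} deduplicated")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for set_id, (desc, members) in collection.sets.items():
            handle.write("\t".join([set_id, desc, *members]) + "\n")


# ------------------------------------------------------------------- network

def read_network(path: PathLike, min_confidence: float = 0.70) -> Network:
    """Read an edge list (TSV ``geneA geneB [confidence]`` or SIF) into a Network.

    Edges with confidence <= ``min_confidence`` are dropped — the filter is a
    strict ``>``, the convention of STRING-style confidence cutoffs.  A missing
    confidence column is treated as 1.0.  Self-loops and duplicate undirected
    edges are removed.
    """
    network = Network()
    is_sif = str(path).lower().endswith(".sif")
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and _looks_like_header(fields):
                continue
            if is_sif:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF row needs source, type, target")
                a, targets, conf = fields[0], fields[2:], 1.0
                for b in targets:
                    if conf > min_confidence:
                        network.add_edge(a, b, conf)
                continue
            if len(fields) == 2:
                a, b, conf = fields[0], fields[1], 1.0
            elif len(fields) >= 3:
                a, b = fields[0], fields[1]
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed confidence {fields[2]!r}") from exc
            else:
                raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
            if conf > min_confidence:
                network.add_edge(a, b, conf)
    return network


def _looks_like_header(fields) -> bool:
    lowered = [f.lower() for f in fields[:3]]
    return any(h in lowered for h in ("genea", "geneb", "source", "target", "confidence", "node1", "node2"))


def write_network(network: Network, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("geneA\tgeneB\tconfidence\n")
        for a, b, conf in network.edges:
            handle.write(f"{a}\t{b}\t{conf:.6g}\n")


# ------------------------------------------------------------ meta-hub table

def read_meta_study_table(path: PathLike) -> MetaStudyTable:
    """Read a long-format TSV with columns study_id, gene_symbol."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ("study_id", "gene_symbol"), path)
    return MetaStudyTable(list(zip(frame["study_id"], frame["gene_symbol"])))


def write_meta_study_table(table: MetaStudyTable, path: PathLike) -> None:
    pd.DataFrame(table.records, columns=["study_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------------ survival

def read_survival_table(path: PathLike) -> SurvivalTable:
    """Read a TSV with columns sample_id, time (days), event (1=death, 0=censored)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(frame, ("sample_id", "time", "event"), path)
    return SurvivalTable(
        list(frame["sample_id"]),
        frame["time"].to_numpy(dtype=float),
        frame["event"].to_numpy(),
    )


def write_survival_table(table: SurvivalTable, path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, "time": table.time, "event": table.event}
    ).to_csv(path, sep="\t", index=False)


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
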