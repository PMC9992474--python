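"""End-to-end orchestration of the key-candidate-gene workflow.

A single structured YAML config drives the full multi-dataset run:

per dataset: normalize -> moderated-t DE -> probe collapse -> DEG filter ->
per-gene SVM -> DEDG selection; then the cross-dataset DEDG intersection;
optional enrichment; PPI network centralities, per-method top-k hub lists and
their five-way consensus; MCODE modules and the hub-module gene union; the
meta-hub frequency table and its significant set; the triple-intersection key
candidate genes; and, when validation data are configured, per-gene ROC/AUC
and median-split survival analysis.

Every stage writes one TSV under the output directory and is recorded in a
manifest with a content hash, so identical configs and seeds reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

import pandas as pd
import yaml

from . import diffexpr, io, metahub, network, svm_filter, validation
from .enrichment import hypergeometric_enrichment
from .mcode import mcode_cluster

logger = logging.getLogger("keygenes")

__all__ = ["DatasetConfig", "PipelineConfig", "run_pipeline"]


@dataclass
class DatasetConfig:
    name: str
    expression: str
    labels: str
    probe_map: Optional[str] = None
    already_logged: bool = True


@dataclass
class PipelineConfig:
    """All paths, thresholds and seeds for a full pipeline run."""

    datasets: List[DatasetConfig]
    network_path: Optional[str] = None
    meta_table_path: Optional[str] = None     # packaged 52-study table if None
    gene_sets_path: Optional[str] = None
    validation_expression: Optional[str] = None
    validation_labels: Optional[str] = None
    survival_path: Optional[str] = None
    out_dir: str = "keygenes_out"

    lfc_cut: float = 1.0
    adjp_cut: float = 0.01
    svm_threshold: float = 80.0
    svm_strict: bool = False
    svm_folds: int = 5
    hub_k: int = 30
    edge_min_conf: float = 0.70
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    mcode_haircut: bool = True
    module_min_score: float = 5.0
    module_min_nodes: int = 5
    meta_min_freq: int = 3
    meta_strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        datasets = [DatasetConfig(**d) for d in raw.pop("datasets", [])]
        return cls(datasets=datasets, **raw)


def _write(frame: pd.DataFrame, path: Path, manifest: List[Dict], stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest.append({"stage": stage, "path": str(path), "sha256": digest})
    logger.info("stage %-28s -> %s", stage, path.name)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the full workflow; returns the manifest as a DataFrame."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: List[Dict] = []
    t0 = time.time()

    dedg_sets: List[Set[str]] = []
    universe: Set[str] = set()
    for ds in config.datasets:
        stage = f"dataset:{ds.name}"
        try:
            X = io.read_expression_matrix(ds.expression)
            labels = io.read_phenotype_table(ds.labels)
            X = diffexpr.log2_quantile_normalize(X, already_logged=ds.already_logged)
            de_probe = diffexpr.fit_moderated_t(X, labels)
            if ds.probe_map:
                probe_map = io.read_probe_map(ds.probe_map)
                adj = dict(zip(de_probe.feature_ids, de_probe.adj_p))
                raw = dict(zip(de_probe.feature_ids, de_probe.p))
                Xg = diffexpr.collapse_probes(X, probe_map, adj, raw)
                de = diffexpr.fit_moderated_t(Xg, labels)
            else:
                Xg, de = X, de_probe
            _write(de.to_frame(), out / f"de_{ds.name}.tsv", manifest, f"{stage}:de")

            up, down = diffexpr.filter_degs(de, config.lfc_cut, config.adjp_cut)
            degs = sorted(up | down)
            universe |= set(Xg.feature_ids)
            deg_frame = pd.DataFrame(
                {"gene": degs, "direction": ["up" if g in up else "down" for g in degs]}
            )
            _write(deg_frame, out / f"degs_{ds.name}.tsv", manifest, f"{stage}:degs")
            if not degs:
                logger.warning("dataset %s produced no DEGs", ds.name)
                dedg_sets.append(set())
                continue

            acc = svm_filter.per_gene_svm_accuracy(
                Xg.subset_features(degs), labels,
                k_folds=config.svm_folds, seed=config.seed,
            )
            _write(acc.to_frame(), out / f"svm_accuracy_{ds.name}.tsv", manifest, f"{stage}:svm")
            dedgs = svm_filter.select_dedgs(acc, config.svm_threshold, config.svm_strict)
            dedg_sets.append(dedgs)
        except Exception as exc:
            _abort(manifest, out, stage, exc)

    common_dedgs = svm_filter.intersect_gene_sets(dedg_sets)
    _write(pd.DataFrame({"gene": sorted(common_dedgs)}),
           out / "common_dedgs.tsv", manifest, "common_dedgs")

    if config.gene_sets_path and common_dedgs:
        try:
            collection = io.read_gene_sets(config.gene_sets_path)
            enr = hypergeometric_enrichment(common_dedgs, collection, universe)
            _write(enr.to_frame(), out / "enrichment.tsv", manifest, "enrichment")
        except Exception as exc:
            _abort(manifest, out, "enrichment", exc)

    central_hubs: Set[str] = set()
    hub_module_genes: Set[str] = set()
    if config.network_path:
        try:
            net = io.read_network(config.network_path, config.edge_min_conf)
            table = network.compute_centralities(net)
            _write(table.to_frame(), out / "centralities.tsv", manifest, "centralities")
            top_lists = {
                m: network.top_k_hubs(table, m, config.hub_k)
                for m in network.CENTRALITY_METHODS
            }
            hub_frame = pd.DataFrame(
                [(m, r + 1, g) for m, lst in top_lists.items() for r, g in enumerate(lst)],
                columns=["method", "rank", "gene"],
            )
            _write(hub_frame, out / "top_hubs.tsv", manifest, "top_hubs")
            central_hubs = svm_filter.intersect_gene_sets(
                [set(lst) for lst in top_lists.values()]
            )
            _write(pd.DataFrame({"gene": sorted(central_hubs)}),
                   out / "central_hub_genes.tsv", manifest, "central_hubs")

            modules = mcode_cluster(
                net,
                degree_cutoff=config.mcode_degree_cutoff,
                node_score_cutoff=config.mcode_node_score_cutoff,
                k_core=config.mcode_k_core,
                max_depth=config.mcode_max_depth,
                haircut=config.mcode_haircut,
            )
            mod_frame = pd.DataFrame(
                [
                    (i + 1, m.score, len(m.nodes), m.n_edges, ",".join(sorted(m.nodes)))
                    for i, m in enumerate(modules)
                ],
                columns=["module_id", "score", "n_nodes", "n_edges", "genes"],
            )
            _write(mod_frame, out / "mcode_modules.tsv", manifest, "mcode")
            _, hub_module_genes = network.select_hub_modules(
                modules, config.module_min_score, config.module_min_nodes
            )
            _write(pd.DataFrame({"gene": sorted(hub_module_genes)}),
                   out / "hub_module_genes.tsv", manifest, "hub_modules")
        except Exception as exc:
            _abort(manifest, out, "network", exc)

    try:
        meta = (
            io.read_meta_study_table(config.meta_table_path)
            if config.meta_table_path
            else metahub.load_packaged_meta_table()
        )
        freqs = metahub.meta_gene_frequencies(meta)
        _write(freqs.to_frame(), out / "meta_frequencies.tsv", manifest, "meta_frequencies")
        significant = metahub.significant_meta_hub(
            freqs, config.meta_min_freq, config.meta_strict
        )
        _write(pd.DataFrame({"gene": sorted(significant)}),
               out / "significant_meta_hub.tsv", manifest, "significant_meta_hub")
    except Exception as exc:
        _abort(manifest, out, "meta_hub", exc)

    key_genes = metahub.key_candidate_genes(central_hubs, hub_module_genes, significant)
    _write(pd.DataFrame({"gene": sorted(key_genes)}),
           out / "key_candidate_genes.tsv", manifest, "key_genes")

    if config.validation_expression and config.validation_labels and key_genes:
        try:
            Xv = io.read_expression_matrix(config.validation_expression)
            lv = io.read_phenotype_table(config.validation_labels)
            rows = []
            for gene in sorted(key_genes):
                if gene in set(Xv.feature_ids):
                    r = validation.per_gene_auc_loocv(Xv, lv, gene)
                    rows.append((r.gene, r.auc, r.ci_low, r.ci_high, r.n_case, r.n_control))
            _write(pd.DataFrame(rows, columns=["gene", "auc", "ci_low", "ci_high", "n_case", "n_control"]),
                   out / "roc_validation.tsv", manifest, "roc")
        except Exception as exc:
            _abort(manifest, out, "roc", exc)

    if config.survival_path and config.validation_expression and key_genes:
        try:
            Xv = io.read_expression_matrix(config.validation_expression)
            surv = io.read_survival_table(config.survival_path)
            rows = []
            for gene in sorted(key_genes):
                if gene in set(Xv.feature_ids):
                    fit = validation.survival_summary(Xv, surv, gene)
                    rows.append((fit.gene, fit.logrank_chi2, fit.logrank_p,
                                 fit.cox_loghr, fit.cox_se, fit.cox_p))
            _write(pd.DataFrame(rows, columns=["gene", "logrank_chi2", "logrank_p",
                                               "cox_loghr", "cox_se", "cox_p"]),
                   out / "survival_validation.tsv", manifest, "survival")
        except Exception as exc:
            _abort(manifest, out, "survival", exc)

    frame = pd.DataFrame(manifest)
    frame.to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info("pipeline finished in %.1f s (%d stages)", time.time() - t0, len(manifest))
    return frame


def _abort(manifest: List[Dict], out: Path, stage: str, exc: Exception) -> None:
    manifest.append({"stage": stage, "path": "", "sha256": f"FAILED: {exc}"})
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
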