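"""Synthetic data generators with planted ground truth.

Every generator emulates one of the data modalities the pipeline consumes —
two-class log2-scale expression with planted differential genes and duplicate
probes, a PPI-like background graph with planted cliques, a study-by-gene
literature table with controlled occurrence frequencies, and exponential
survival times whose log-hazard depends on selected genes — and returns the
planted truth so recovery can be asserted.

Design notes: expression noise is Gaussian on the log2 scale (normalized
microarray intensities are approximately Gaussian after log2, unlike raw
sequencing counts); planted differential shifts alternate in sign so both up-
and down-regulated genes exist; each generator draws from its own explicitly
seeded :class:`numpy.random.Generator` and never touches global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import (
    ExpressionMatrix,
    MetaStudyTable,
    Network,
    PhenotypeTable,
    SurvivalTable,
)

__all__ = [
    "SimulationTruth",
    "simulate_expression_dataset",
    "simulate_ppi_network",
    "simulate_meta_table",
    "simulate_survival",
]


@dataclass
class SimulationTruth:
    """Planted ground truth emitted alongside each simulated dataset."""

    de_genes: Dict[str, float] = field(default_factory=dict)      # gene -> log2 shift
    clique_genes: List[Set[str]] = field(default_factory=list)
    gene_frequencies: Dict[str, int] = field(default_factory=dict)
    hazard_genes: Dict[str, float] = field(default_factory=dict)  # gene -> beta


def simulate_expression_dataset(
    n_genes: int,
    n_case: int,
    n_control: int,
    de_fraction: float = 0.1,
    delta: float = 2.0,
    sigma: float = 0.5,
    dup_probe_rate: float = 0.1,
    seed: int = 0,
    planted_genes: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionMatrix, PhenotypeTable, Dict[str, str], SimulationTruth]:
    """Two-class probe-level expression with planted differential genes.

    Gene g has background mean mu_g ~ Uniform(6, 10) on the log2 scale and
    Gaussian noise sigma; a de_fraction of genes get a mean shift of +/-delta
    in cases, with alternating signs.  A dup_probe_rate fraction of genes
    receive a second probe with the same mean and independent noise.  Returns
    (probe-level matrix, phenotype labels, probe->gene map, truth).

    ``planted_genes`` overrides the random choice of differential genes
    (gene ids are ``G00000`` ... ``G{n-1:05d}``); this is how multi-dataset
    simulations share one set of true genes across independent noise draws.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample counts must be positive")
    if not 0.0 < de_fraction < 1.0:
        raise ValueError("de_fraction must lie strictly between 0 and 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    mu = rng.uniform(6.0, 10.0, size=n_genes)
    if planted_genes is not None:
        index = {g: i for i, g in enumerate(genes)}
        missing = [g for g in planted_genes if g not in index]
        if missing:
            raise ValueError(f"planted genes outside the simulated universe: {missing[:5]}")
        de_idx = np.array([index[g] for g in planted_genes])
    else:
        n_de = int(round(n_genes * de_fraction))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
    shift = np.zeros(n_genes)
    for rank, gi in enumerate(sorted(de_idx)):
        shift[gi] = delta if rank % 2 == 0 else -delta

    n_samples = n_case + n_control
    labels = np.array([1] * n_case + [0] * n_control)
    sample_ids = [f"case{i:03d}" for i in range(n_case)] + [
        f"ctrl{i:03d}" for i in range(n_control)
    ]

    probe_ids: List[str] = []
    probe_map: Dict[str, str] = {}
    rows: List[np.ndarray] = []

    def gene_row(gi: int) -> np.ndarray:
        means = mu[gi] + shift[gi] * labels
        return rng.normal(means, sigma)

    dup = rng.random(n_genes) < dup_probe_rate
    for gi, gene in enumerate(genes):
        probe = f"P{gi:05d}_1"
        probe_ids.append(probe)
        probe_map[probe] = gene
        rows.append(gene_row(gi))
        if dup[gi]:
            probe2 = f"P{gi:05d}_2"
            probe_ids.append(probe2)
            probe_map[probe2] = gene
            rows.append(gene_row(gi))

    X = ExpressionMatrix(probe_ids, sample_ids, np.vstack(rows))
    phen = PhenotypeTable(sample_ids, labels)
    truth = SimulationTruth(
        de_genes={genes[gi]: float(shift[gi]) for gi in sorted(de_idx) if shift[gi] != 0.0}
    )
    return X, phen, probe_map, truth


def simulate_ppi_network(
    genes: Sequence[str],
    background_edge_p: float = 0.02,
    planted_cliques: Sequence[Sequence[str]] = (),
    seed: int = 0,
) -> Tuple[Network, SimulationTruth]:
    """Erdős–Rényi background graph plus fully connected planted cliques.

    Edge confidences are drawn Uniform(0.71, 1.0) so every simulated edge
    survives the standard > 0.70 confidence filter.
    """
    if not 0.0 <= background_edge_p <= 1.0:
        raise ValueError("background_edge_p must lie in [0, 1]")
    genes = [str(g) for g in genes]
    gene_set = set(genes)
    for clique in planted_cliques:
        if len(clique) < 3:
            raise ValueError("planted cliques must have at least 3 members")
        if not set(clique) <= gene_set:
            raise ValueError("clique members must be drawn from the gene list")

    rng = np.random.default_rng(seed)
    network = Network(nodes=genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < background_edge_p:
                network.add_edge(genes[i], genes[j], float(rng.uniform(0.71, 1.0)))
    for clique in planted_cliques:
        members = sorted(set(clique))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                network.add_edge(members[i], members[j], float(rng.uniform(0.71, 1.0)))
    truth = SimulationTruth(clique_genes=[set(map(str.upper, c)) for c in planted_cliques])
    return network, truth


def simulate_meta_table(
    gene_pool: Sequence[str],
    n_studies: int,
    target_frequencies: Dict[str, int],
    seed: int = 0,
) -> MetaStudyTable:
    """Study-gene table where gene g appears in exactly target_frequencies[g] studies.

    The studies listing each gene are chosen uniformly at random without
    replacement, so per-gene counts are exact by construction.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    for g, f in target_frequencies.items():
        if f < 0 or f > n_studies:
            raise ValueError(f"frequency {f} for gene {g!r} outside [0, {n_studies}]")
    rng = np.random.default_rng(seed)
    studies = [f"study{i:03d}" for i in range(n_studies)]
    records = []
    for gene in gene_pool:
        f = target_frequencies.get(str(gene), 0)
        if f == 0:
            continue
        chosen = rng.choice(n_studies, size=f, replace=False)
        for si in sorted(chosen):
            records.append((studies[si], str(gene)))
    return MetaStudyTable(records)


def simulate_survival(
    expr: ExpressionMatrix,
    beta: Dict[str, float],
    baseline_hazard: float = 0.001,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival with per-sample rate baseline * exp(sum beta_g x_g).

    Censoring is independent Uniform(0, tau), with tau calibrated by
    bisection so the expected censored fraction approximates ``censor_rate``;
    censor_rate = 0 disables censoring entirely.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    missing = [g for g in beta if g not in set(expr.feature_ids)]
    if missing:
        raise ValueError(f"hazard genes absent from the expression matrix: {missing}")

    rng = np.random.default_rng(seed)
    eta = np.zeros(len(expr.sample_ids))
    for gene, b in beta.items():
        x = expr.row(gene)
        eta += b * (x - x.mean())  # center so baseline_hazard stays interpretable
    rates = baseline_hazard * np.exp(eta)
    times = rng.exponential(1.0 / rates)

    if censor_rate == 0.0:
        return SurvivalTable(list(expr.sample_ids), times, np.ones(len(times), dtype=int))

    # Censoring means C < T; for rate l, P(T > C) = (1 - e^{-l tau}) / (l tau),
    # which decreases from 1 to 0 as tau grows.
    def censored_fraction(tau: float) -> float:
        z = rates * tau
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-9, 1.0 / baseline_hazard
    while censored_fraction(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12 / baseline_hazard:
            break
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    censor_times = rng.uniform(0.0, tau, size=len(times))
    event = (times <= censor_times).astype(int)
    observed = np.minimum(times, censor_times)
    return SurvivalTable(list(expr.sample_ids), observed, event)
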