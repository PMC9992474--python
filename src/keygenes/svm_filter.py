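"""Per-gene SVM discriminative filtering of differentially expressed genes.

Each candidate gene is evaluated *on its own* as the single input feature of
a soft-margin SVM with RBF kernel.  The reported score is the best stratified
k-fold cross-validation accuracy over a small log-spaced grid of (C, gamma);
genes whose accuracy passes the threshold (default 80%) are kept as
differentially expressed discriminative genes (DEDGs).  The feature is
standardized on the training folds only, because the RBF bandwidth gamma is
scale-sensitive and a shared grid is only meaningful on a common scale.

Reported accuracy is the maximum over the grid (not nested CV), which is
mildly optimistic; the filter cares about ranking genes, not about unbiased
generalization estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Set

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ExpressionMatrix, PhenotypeTable

__all__ = [
    "GeneAccuracyTable",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "per_gene_svm_accuracy",
    "select_dedgs",
    "intersect_gene_sets",
]

DEFAULT_C_GRID = [2.0**-3, 2.0**-1, 2.0**1, 2.0**3, 2.0**5]
DEFAULT_GAMMA_GRID = [2.0**-7, 2.0**-5, 2.0**-3, 2.0**-1, 2.0**1]


@dataclass
class GeneAccuracyTable:
    """Cross-validated single-gene classification accuracies, sorted descending.

    Accuracies are percentages in [0, 100]; best_C/best_gamma record the grid
    point that achieved each gene's maximum.
    """

    genes: List[str]
    cv_accuracy: np.ndarray
    best_C: np.ndarray
    best_gamma: np.ndarray

    def __post_init__(self) -> None:
        self.cv_accuracy = np.asarray(self.cv_accuracy, dtype=float)
        self.best_C = np.asarray(self.best_C, dtype=float)
        self.best_gamma = np.asarray(self.best_gamma, dtype=float)
        if np.any((self.cv_accuracy < 0) | (self.cv_accuracy > 100)):
            raise ValueError("accuracies must lie in [0, 100]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.genes,
                "cv_accuracy": self.cv_accuracy,
                "best_C": self.best_C,
                "best_gamma": self.best_gamma,
            }
        )


def per_gene_svm_accuracy(
    X: ExpressionMatrix,
    labels: PhenotypeTable,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k_folds: int = 5,
    seed: int = 0,
) -> GeneAccuracyTable:
    """Grid-searched stratified k-fold CV accuracy of a univariate RBF-SVM per gene.

    Fold assignment is deterministic for a fixed seed and shared across genes
    and grid points, so accuracies are comparable.  The output is sorted by
    descending accuracy (ties: lexicographic gene id).
    """
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("C and gamma grids must be non-empty")
    labels.require_both_classes()
    y = labels.aligned_to(X.sample_ids)
    n_minority = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_minority < k_folds:
        raise ValueError(
            f"minority class has {n_minority} samples; cannot stratify into {k_folds} folds"
        )
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros(len(y)), y))

    genes, accs, cs, gs = [], [], [], []
    for i, gene in enumerate(X.feature_ids):
        feature = X.values[i].reshape(-1, 1)
        best = (-1.0, np.nan, np.nan)
        for C in C_grid:
            for gamma in gamma_grid:
                model = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf"))
                scores = cross_val_score(model, feature, y, cv=iter(folds), scoring="accuracy")
                acc = 100.0 * float(scores.mean())
                if acc > best[0]:
                    best = (acc, C, gamma)
        genes.append(gene)
        accs.append(best[0])
        cs.append(best[1])
        gs.append(best[2])

    order = sorted(range(len(genes)), key=lambda k: (-accs[k], genes[k]))
    return GeneAccuracyTable(
        [genes[k] for k in order],
        np.array([accs[k] for k in order]),
        np.array([cs[k] for k in order]),
        np.array([gs[k] for k in order]),
    )


def select_dedgs(
    table: GeneAccuracyTable, threshold_pct: float = 80.0, strict: bool = False
) -> Set[str]:
    """Genes whose CV accuracy passes the threshold.

    The default comparison is >= (a gene at exactly 80.0% is kept); pass
    ``strict=True`` for a strict > comparison.
    """
    if strict:
        keep = table.cv_accuracy > threshold_pct
    else:
        keep = table.cv_accuracy >= threshold_pct
    return {g for g, k in zip(table.genes, keep) if k}


def intersect_gene_sets(sets: Sequence[Set[str]]) -> Set[str]:
    """Exact intersection of one or more gene sets (order-independent).

    Used for the cross-dataset DEDG consensus, the five-centrality hub
    consensus, and the final key-candidate-gene triple intersection alike.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("at least one gene set is required")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out
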