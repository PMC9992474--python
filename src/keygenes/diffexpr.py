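"""Differential expression with empirical-Bayes moderated t-statistics.

Implements the standard microarray workflow for two-group comparisons:
quantile normalization on the log2 scale, a per-gene two-sample linear model
whose residual variances are shrunk toward a common prior by the closed-form
moment estimator on log-variances, Benjamini-Hochberg FDR adjustment, a
minimum-adjusted-p probe-to-gene collapsing rule, and the DEG filter
|log2FC| > 1 and adjusted p < 0.01 (both strict).

The variance shrinkage models the gene-wise sample variances as scaled
chi-squared draws around a common prior variance s0^2 with prior degrees of
freedom d0; the posterior variance for gene g with d_g residual df is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t uses d0 + d_g degrees of freedom.  (d0, s0^2) are
estimated by matching the mean and variance of log s_g^2 against the
log-chi-squared distribution (digamma/trigamma moments), with the trigamma
inverse obtained by Newton iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, PhenotypeTable

__all__ = [
    "DEResult",
    "log2_quantile_normalize",
    "fit_moderated_t",
    "adjust_bh",
    "collapse_probes",
    "filter_degs",
]


@dataclass
class DEResult:
    """Per-feature differential expression summary.

    log2fc is case mean minus control mean on the log2 scale.  d0 and s02 are
    the prior degrees of freedom and prior variance of the empirical-Bayes
    shrinkage (d0 may be ``inf`` when the observed log-variances are less
    dispersed than pure chi-squared noise).
    """

    feature_ids: List[str]
    log2fc: np.ndarray
    mod_t: np.ndarray
    p: np.ndarray
    adj_p: np.ndarray
    d0: float
    s02: float

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "log2fc": self.log2fc,
                "mod_t": self.mod_t,
                "p": self.p,
                "adj_p": self.adj_p,
            }
        )

    def subset(self, features: List[str]) -> "DEResult":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in features]
        return DEResult(
            features,
            self.log2fc[rows],
            self.mod_t[rows],
            self.p[rows],
            self.adj_p[rows],
            self.d0,
            self.s02,
        )


def log2_quantile_normalize(X: ExpressionMatrix, already_logged: bool = True) -> ExpressionMatrix:
    """Log2-transform (optionally) and quantile-normalize sample columns.

    After normalization every column shares the identical sorted value
    vector: rank r in each column is replaced by the mean across columns of
    each column's r-th order statistic.  Ties within a column receive the
    mean of their tied ranks' replacement values (average-rank convention).
    """
    values = X.values
    if not already_logged:
        if np.any(values <= 0):
            raise ValueError("nonpositive values cannot be log2-transformed")
        values = np.log2(values)
    sorted_cols = np.sort(values, axis=0)
    target = sorted_cols.mean(axis=1)  # mean r-th order statistic
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return ExpressionMatrix(list(X.feature_ids), list(X.sample_ids), out)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting points 1/sqrt(y) (small y) and 1/y (large y)
    and the monotone Newton update on the reciprocal scale, which converges in
    a handful of iterations for all practical y.
    """
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-10):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment estimator of (d0, s0^2) from gene-wise variances with df residual df.

    Matches mean/variance of log(s2) to the scaled log-chi-squared model.
    Returns d0 = inf when the empirical dispersion of log-variances does not
    exceed the chi-squared sampling noise (no gene-to-gene variance spread).
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(s2[s2 > 0])
    if z.size == 0:
        raise ValueError("all gene variances are zero; shrinkage prior cannot be estimated")
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def fit_moderated_t(
    X: ExpressionMatrix,
    labels: PhenotypeTable,
    d0_override: Optional[float] = None,
) -> DEResult:
    """Two-group moderated t-test per feature with empirical-Bayes shrinkage.

    ``d0_override`` pins the prior degrees of freedom (0 recovers the ordinary
    pooled-variance t; ``inf`` forces every gene to the prior variance), which
    is mainly useful for verifying the limiting behaviour.
    """
    labels.require_both_classes()
    y = labels.aligned_to(X.sample_ids)
    case, ctrl = X.values[:, y == 1], X.values[:, y == 0]
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("at least 2 samples per class are required")
    df = n1 + n0 - 2
    m1, m0 = case.mean(axis=1), ctrl.mean(axis=1)
    beta = m1 - m0
    rss = ((case - m1[:, None]) ** 2).sum(axis=1) + ((ctrl - m0[:, None]) ** 2).sum(axis=1)
    s2 = rss / df

    if d0_override is None:
        d0, s02 = estimate_variance_prior(s2, df)
    else:
        d0 = float(d0_override)
        _, s02 = estimate_variance_prior(s2, df) if np.any(s2 > 0) else (np.inf, float(np.mean(s2)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    stderr = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, beta / stderr, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = adjust_bh(p)
    return DEResult(list(X.feature_ids), beta, t, p, adj, d0, s02)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(
    X: ExpressionMatrix,
    probe_map: Dict[str, str],
    probe_adj_p: Dict[str, float],
    probe_raw_p: Optional[Dict[str, float]] = None,
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by minimum adjusted p-value.

    When several probes map to the same gene the probe with the smallest
    adjusted p is retained; ties are broken by smaller raw p, then by
    lexicographic probe id, so the outcome is deterministic.  Probes without
    a gene mapping are dropped.
    """
    missing = [pr for pr in X.feature_ids if pr in probe_map and pr not in probe_adj_p]
    if missing:
        raise ValueError(f"probes without adjusted p-values: {missing[:5]}")
    best: Dict[str, Tuple] = {}
    for i, probe in enumerate(X.feature_ids):
        gene = probe_map.get(probe)
        if gene is None:
            continue
        raw = probe_raw_p.get(probe, np.inf) if probe_raw_p else np.inf
        key = (probe_adj_p[probe], raw, probe)
        if gene not in best or key < best[gene][0]:
            best[gene] = (key, i)
    genes = sorted(best)
    rows = [best[g][1] for g in genes]
    return ExpressionMatrix(genes, list(X.sample_ids), X.values[rows])


def filter_degs(
    de: DEResult, lfc_cut: float = 1.0, adjp_cut: float = 0.01
) -> Tuple[Set[str], Set[str]]:
    """Split features into up/down-regulated DEG sets (strict inequalities).

    up = {g : log2fc > lfc_cut and adj_p < adjp_cut};
    down = {g : log2fc < -lfc_cut and adj_p < adjp_cut}.
    """
    up = {
        f
        for f, lfc, ap in zip(de.feature_ids, de.log2fc, de.adj_p)
        if lfc > lfc_cut and ap < adjp_cut
    }
    down = {
        f
        for f, lfc, ap in zip(de.feature_ids, de.log2fc, de.adj_p)
        if lfc < -lfc_cut and ap < adjp_cut
    }
    return up, down
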