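"""Differential expression on a simulated two-class microarray dataset.

Simulates 300 genes (30 planted with a +/-3 log2-unit shift) measured on
30 cases and 30 controls, quantile-normalizes, collapses duplicate probes to
genes by minimum adjusted p, fits the empirical-Bayes moderated t-test and
applies the DEG filter |log2FC| > 1, adjusted p < 0.01.
"""

from keygenes import (
    collapse_probes,
    filter_degs,
    fit_moderated_t,
    log2_quantile_normalize,
    simulate_expression_dataset,
)

X, labels, probe_map, truth = simulate_expression_dataset(
    n_genes=300, n_case=30, n_control=30, de_fraction=0.1,
    delta=3.0, sigma=0.5, dup_probe_rate=0.1, seed=1,
)
Xn = log2_quantile_normalize(X)
de_probe = fit_moderated_t(Xn, labels)
adj = dict(zip(de_probe.feature_ids, de_probe.adj_p))
raw = dict(zip(de_probe.feature_ids, de_probe.p))
Xg = collapse_probes(Xn, probe_map, adj, raw)
de = fit_moderated_t(Xg, labels)
up, down = filter_degs(de)

planted = set(truth.de_genes)
detected = up | down
print(f"probes: {len(X.feature_ids)}, genes after collapse: {len(Xg.feature_ids)}")
print(f"shrinkage prior: d0 = {de.d0:.1f} df, s0^2 = {de.s02:.3f}")
print(f"DEGs: {len(up)} up, {len(down)} down (planted: {len(planted)})")
print(f"planted genes recovered: {len(detected & planted)}/{len(planted)}, "
      f"false positives: {len(detected - planted)}")
# The prior df d0 measures how much gene variances are shrunk toward the
# common prior s0^2; recovery near 30/30 with ~0 false positives shows the
# filter operating in its intended regime.
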