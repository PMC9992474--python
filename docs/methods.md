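# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the behaviour of the synthetic-data generators, and the
numerical conventions and known limitations. Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`.

## Normalization and differential expression

**Quantile normalization.** After optional log2 transformation, rank *r* of
each sample column is replaced by the mean across columns of the *r*-th
order statistics; ties receive the mean of their tied ranks' replacement
values (average-rank convention). This makes every column's sorted vector
identical to machine precision, and matches the reference microarray
implementation on tied inputs. Nonpositive values are fatal when a log2
transform is requested; missing values are fatal everywhere — microarray
series matrices are complete, and silent imputation would change the
inference.

**Moderated t.** Per gene, the two-group linear model gives
β̂_g = x̄_case − x̄_control and a pooled residual variance s²_g with
d_g = n₁+n₂−2 df. The empirical-Bayes prior (d₀, s₀²) is estimated by the
closed-form moment method on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2),

    ψ′(d₀/2) = var(e) − ψ′(d_g/2),    s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)),

where the trigamma inverse is solved by Newton iteration. When the
dispersion of log-variances does not exceed chi-squared sampling noise, d₀
is infinite and every gene uses s₀². The posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) yields t̃ with d₀+d_g df. The fixed
variant is plain shrinkage — no mean-variance trend, no robust
down-weighting. The implementation reproduces the reference
empirical-Bayes implementation (limma 3.58.1) to 7 significant digits on a
frozen 8-gene fixture, collapses to the ordinary pooled t as d₀ → 0, and is
calibrated under the null (type-I error 5% ± 1% at 5,000 genes).

**Probe collapsing.** DE is fitted at probe level first; per gene the probe
with the smallest adjusted p is kept (ties: smaller raw p, then
lexicographic probe id), and gene-level DE is then re-fitted on the
retained rows. The rule references *adjusted* p per probe, which forces the
probe-level fit to come first.

**DEG filter.** up = {log2FC > 1 and adj. p < 0.01}, down analogously; both
inequalities strict, both cutoffs configurable.

## Per-gene SVM filtering

Each candidate gene is the sole feature of a soft-margin RBF-SVM
(K(x_i,x_j) = exp(−γ‖x_i−x_j‖²)). Accuracy is stratified k-fold (default 5)
CV, maximized over a log-spaced grid C ∈ {2⁻³,2⁻¹,2,2³,2⁵},
γ ∈ {2⁻⁷,…,2¹}; folds are fixed per seed and shared across genes and grid
points so scores are comparable. The feature is standardized on training
folds only (γ is scale-sensitive; a shared grid needs a common scale),
which also makes scores invariant to positive affine transforms of a gene.

Reporting the **maximum** over the grid (no nested CV) is mildly
optimistic: the bias is roughly one CV-noise standard deviation, measured
at ≈ +8 accuracy points for 50 samples and ≈ +3.5 at 200 samples on pure
noise genes. The filter ranks genes rather than estimating generalization
error, so this optimism is acceptable and is documented rather than
corrected; the null-behaviour check therefore uses 200 samples, where the
grid-max optimism is small against the 80% selection threshold.

The DEDG threshold defaults to ≥ 80.0% with a flag for strict >; both
conventions appear in practice.

## Enrichment

Over-representation of a query list against GMT sets is the upper-tail
hypergeometric P(X ≥ k) with N = |universe|, K = |set ∩ universe|,
n = |query|, verified against exhaustive enumeration for N ≤ 12. Raw p
with p < 0.05 and top-5 reporting mirrors common web-tool output; BH
correction is available but off by default. The universe defaults to the
platform's post-collapse gene list, the standard ORA choice.

## Network stage

Centralities are computed on the unweighted simple graph (confidences
matter only at the > 0.70 edge filter, strict inequality):

* degree; MNC(v) = largest connected component of the subgraph induced by
  N(v); MCC(v) = Σ over maximal cliques C ∋ v of (|C|−1)!, with isolated
  nodes at 1 (their singleton clique);
* closeness is **harmonic** (Σ 1/d, 1/∞ = 0) because PPI graphs are
  routinely disconnected and classical closeness is ill-defined there;
* betweenness counts each unordered pair once.

All five agree with brute-force enumeration oracles on 200 random graphs of
≤ 9 nodes. Top-k lists (default k = 30) are tie-broken by degree then node
id and are prefix-stable in k.

**MCODE.** Vertex weight = k_max × density of the highest k-core of the
closed neighborhood (0 below the degree cutoff); complexes grow
breadth-first from the heaviest unvisited seed, admitting unvisited
neighbors with weight ≥ seed weight × (1 − node score cutoff), to the depth
limit; complexes without a 2-core are discarded; haircut iteratively trims
singly connected nodes; fluff is off by default because the standard
parameterization selects haircut. Score = density × node count, so a
clique K_m scores exactly m — the K₆ worked example returns one module of 6
nodes, 15 undirected edges, score 6.0. Module filters default to
score ≥ 5 and nodes ≥ 5; the stricter ≥ 6/≥ 6 reading is available via the
same arguments, and both select a planted 6-clique.

## Meta-hub analysis

Frequencies count **distinct studies** per gene (within-study duplicates
collapse at ingestion); the significance threshold defaults to ≥ 3 with a
strict-> option, and both counts are reported side by side where it
matters. Gene symbols are uppercased everywhere because curated tables mix
cases. The packaged 52-study table is transcribed verbatim, typos included;
its provenance note records the rows whose stated counts disagree with
their listed genes and the resulting union/threshold counts (212 genes,
45 at ≥ 3, 36 at > 3). The key-gene operation is a plain triple
intersection and is commutative, associative and monotone.

## Validation

**ROC.** Leave-one-out CV: each sample is scored by a univariate logistic
model fit on the others; the AUC is the Mann–Whitney statistic of the
held-out scores (ties ½) with a 95% CI from the DeLong variance estimator
(deterministic, matching the common ROC tool's default; verified against it
on a frozen fixture). Three numerical choices matter and are deliberate:

* scores are held-out **linear predictors**, rank-identical to predicted
  probabilities (the same sigmoid maps them in every fold) but immune to
  floating-point saturation at probabilities 0/1;
* **balanced class weights** remove the class-prior artifact — without
  them, a held-out sample's own class is underrepresented (49 vs 50) in
  training, and whenever the slope is weak the pooled scores anti-separate,
  collapsing the null AUC to 0;
* **moderate ridge** (C = 1) keeps the slope stable across folds; the
  unpenalized MLE slope swings on near-separable data and inverts pooled
  ranks. With this configuration the LOOCV AUC equals the raw-expression
  Mann–Whitney AUC on separable simulations.

Limitation, measured and accepted: pooled LOO scores remain correlated
across folds, which roughly doubles the null AUC dispersion relative to a
raw AUC (sd 0.115 vs 0.058 at n = 100) and drops DeLong coverage of 0.5 to
~83% under permuted labels, independent of regularization strength. Callers
comparing weak markers should prefer the raw-expression AUC; the LOOCV
variant is faithful to the validation protocol it mirrors.

**Survival.** Samples split at the gene's median (at-median → "low";
configurable); Kaplan–Meier product-limit curves per group; the two-sample
log-rank test; and a univariate Cox model on the continuous expression,
maximized by Newton–Raphson on the partial likelihood with **Breslow** tie
handling (the simplest well-defined convention) and a Wald p. The Cox fit
matches the reference survival implementation to 7 decimals on a frozen
tied-data fixture and agrees with an independent library on tie-free data.
Both log-rank and Cox p-values are reported because published survival
figures rarely say which produced their annotations. Parameter recovery on
simulated data (β = 1, n = 200, 20% censoring) is unbiased with calibrated
standard errors (mean estimate 1.004, sd 0.097, mean SE 0.103); the ±0.2
recovery band is ~1.94σ, so its per-replicate hit rate is ~95% by
construction and is asserted with a binomial tolerance.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, with
full determinism per seed and no global RNG state:

* **Expression**: Gaussian noise on the log2 scale (normalized microarray
  intensities are approximately Gaussian after log2 — not
  negative-binomial counts), background means Uniform(6, 10), planted
  shifts ±δ with alternating signs so both regulation directions exist,
  optional duplicate probes with independent noise. Defaults δ = 2,
  σ = 0.5, 10% differential, 10% duplicated probes. An explicit
  `planted_genes` list lets multiple datasets share one truth, which is how
  multi-dataset consensus runs are simulated.
* **Network**: Erdős–Rényi background plus fully connected planted
  cliques; confidences Uniform(0.71, 1) so simulated edges survive the
  0.70 filter. At background p ≤ 0.02 a planted 6-clique is returned by
  MCODE as the top module with score 6.
* **Meta table**: each gene appears in exactly its target number of
  studies, chosen uniformly — frequency recovery is exact by construction.
* **Survival**: exponential times with rate λ·exp(Σβ_g x_g) (covariates
  centered so the baseline rate stays interpretable); censoring is
  independent Uniform(0, τ) with τ calibrated by bisection to the requested
  censored fraction (±5% at n = 4000).

What the generators do **not** emulate: batch effects, array spatial
artifacts, probe cross-hybridization, heavy-tailed or count noise,
gene–gene correlation beyond the planted structure, and non-proportional
hazards. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data pathologies.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to make the asserted
properties statistically sharp: 20 replicates of 300 genes × 60 samples for
DEG recovery (sensitivity ≥ 95%, FDR ≤ 5% pooled), 60 null genes × 200
samples for the SVM null, 100 LOOCV replicates at n = 100, 200 Cox
replicates at n = 200, 50 log-rank replicates at n = 400 (power ≥ 95% at
hazard ratio 3). Newton iterations (trigamma inverse, Cox) run to 1e-9/1e-10
relative tolerance with 50-iteration caps; non-convergent Cox fits
(monotone likelihood) raise rather than return an estimate. All
tie-breaking (probe collapsing, hub ranking, module ordering) is
deterministic so identical configs and seeds reproduce byte-identical
output tables, which the pipeline manifest verifies by content hash.
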