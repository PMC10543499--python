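# Methods

## Overview

`insuclust` implements a pipeline for dissecting the genetic heterogeneity of
fasting-insulin (FI) levels: variants associated with FI are clustered by
their association profiles across dozens of metabolic traits using Bayesian
non-negative matrix factorization (bNMF) with automatic relevance
determination (ARD); each cluster is converted into a partitioned polygenic
score (pPS); and cluster–outcome associations are estimated per cohort and
pooled by inverse-variance-weighted (IVW) fixed-effects meta-analysis.
Because the individual-level cohorts this kind of study relies on are
access-restricted, the package ships a synthetic-data generator that plants a
known factor structure and known score→outcome effects, so every stage can be
exercised and validated end to end.

## Input matrix construction

Variants enter the analysis when their FI association has p < 5e-5 (strict
inequality).  Every trait Z-score (beta/SE) is oriented to the variant's
FI-increasing allele, defined from the FI record: the effect allele when the
FI beta is non-negative, the other allele otherwise.  Orientation of a trait
record against the FI record compares the full allele pair; strand
complements are accepted only for unambiguous (non-palindromic) pairs —
complement matching is undecidable for A/T and C/G variants, which are
alignable by labels alone at this stage (the frequency safeguard lives in the
scoring engine, where a reference panel is available).

Traits are then pruned so that no two retained Z-score columns have absolute
Pearson correlation at or above 0.85 (pairwise-complete over non-missing
rows).  The pruning is a greedy pass in input order with the FI trait
anchored first; this makes the retained set deterministic and reproducible.
Zero-variance columns are retained with a warning and excluded from
correlation comparisons.

NMF requires non-negative input, but trait Z-scores are signed.  Each trait
column is therefore doubled into a positive and a negative half
(`X[v, t_pos] = max(Z, 0)`, `X[v, t_neg] = max(-Z, 0)`), preserving effect
direction for interpretation; missing associations contribute zero to both
halves (absence of evidence adds no loading).  After factorization the
pos/neg halves of each trait are re-merged into one signed trait weight
(pos minus neg).

A consequence worth noting: the pos/neg doubling is only *exactly* low-rank
for signed matrices in which no entry receives contributions of mixed sign.
When two latent factors hit the same variant–trait cell with opposite signs,
rectification leaves a residual that no rank-K non-negative product can
absorb.  Reconstruction-error expectations for noise-free planted inputs
therefore apply to well-separated (disjoint-support) factors only.

## Bayesian NMF with automatic relevance determination

The factorization model is

    X_ij ~ Normal((W H)_ij, sigma^2),  W, H >= 0,

with half-normal priors on column k of W and row k of H sharing a relevance
parameter lambda_k, and an inverse-gamma(a, b) hyperprior on each lambda_k.
MAP estimation uses multiplicative updates:

    W <- W * (X H') / (W H H' + sigma^2 W Lambda^-1)
    H <- H * (W' X) / (W' W H + sigma^2 Lambda^-1 H)
    lambda_k <- (0.5 ||W_k||^2 + 0.5 ||H_k||^2 + b) / ((n + m)/2 + a + 1)
    sigma^2 <- max(RSS / (n m), sigma2_floor * mean(X^2))

Each sweep is a block coordinate-descent step (the W/H updates are
majorize–minimize steps, the lambda and sigma^2 updates exact minimizers), so
the negative log-posterior trace is non-increasing.  Components whose
combined column/row norm falls below `prune_eps` (default `1e-6 ||X||_F`) at
convergence are zeroed; the number of surviving components is the effective
rank K.  Across `n_restarts` random restarts, the most probable K (ties
toward the smaller K, for parsimony) is identified and the restart with the
lowest final objective at that K is selected.

Defaults and why:

- `k0 = 20`: well above the expected number of clusters, so the rank is
  data-determined from above.
- `a = 25`, `b = mean(X)`: the hyperprior shape controls how strongly
  relevance parameters are pulled toward the prior scale, i.e. the effective
  complexity penalty.  Calibrated on planted fixtures: `a = 10` leaves the
  penalty too weak (one to two surplus noise-chasing components survive),
  `a >= 50` collapses genuine factors.
- `tol = 1e-9` relative objective change, `max_iter = 10,000`: near-duplicate
  components merge slowly; a looser tolerance (1e-7) can stop a fit while
  duplicates are still separating, inflating the effective K.
- `sigma2_floor = 1e-3` (fraction of `mean(X^2)`): on (near-)noiseless inputs
  the MAP noise variance collapses toward zero, which switches the ARD
  penalty off entirely and leaves redundant components unpruned.  The floor
  is far below any realistic residual level for noisy Z-score matrices and is
  inert there.
- Initialization: W, H iid uniform(0,1), jointly rescaled so that
  `mean(W H) = mean(X)` — avoids pruning everything in the first sweeps.
- `warmup = 0`: a short un-regularized warm-up is available (and needed for
  exactly low-rank, noise-free inputs, where the large initial residual
  otherwise kills every component before it reaches the signal), but it is
  off by default because components that establish themselves during warm-up
  are never pruned afterwards, which destroys rank selection on noisy input.
  `BnmfHyperparams.noise_free()` bundles the settings appropriate for clean
  matrices (`warmup=15, sigma2_floor=0.1, tol=1e-10`).

Component death in this scheme is essentially an early-phase competition:
once a component carries substantial signal mass, multiplicative updates will
not remove it (and a zeroed component can never revive).  This is the known
trade-off of multiplicative ARD-NMF; consensus approaches (bootstrapped
restarts) are out of scope here, and the restart-mode selection plays that
stabilizing role.

## Cluster definitions

Cluster membership uses a weight cutoff: variants with weight >= cutoff and
traits with |signed weight| >= cutoff characterize a cluster (a variant may
belong to several clusters; clusters emptied by the cutoff are flagged, never
renumbered).  The default cutoff 0.84 is the value used with the real study
data.  A data-driven alternative pools all variant weights and absolute trait
weights, sorts the distinct values in descending order, and takes the value
at the elbow — the point of maximum perpendicular distance to the chord
joining the largest and smallest values.  Distinct values (rather than all
copies) define the curve; with exactly two distinct values the transition is
the elbow and the larger value is returned, and a constant weight vector is
returned as-is with a warning.

## Partitioned polygenic scores

`score(i, c) = sum_v w_v * oriented_dosage(i, v)` over the cluster's resolved
variants, where the oriented dosage counts the FI-increasing allele (dosage
if the panel effect allele is the counted allele, else `2 - dosage`).
Missing genotypes are imputed as twice the oriented allele frequency
(standard polygenic-score convention).  Scores are reported on the raw
weight-times-dosage scale; association estimates are presented per 10 score
units.

Resolution against a panel, per cluster variant:

1. **Direct** when present and allele-reconcilable.  Palindromic variants are
   additionally required to have a panel FI-allele frequency within
   `freq_tol = 0.05` of the reference frequency *and* outside
   (0.5 − freq_tol, 0.5 + freq_tol); near-0.5 palindromes are undecidable.
2. **Proxy** otherwise: the panel variant with maximal r² >= 0.8 in the LD
   reference (ties by distance, then ID).  With r² only, phase is lost; the
   counted proxy allele is chosen by frequency matching against the
   reference frequency of the original FI-increasing allele, and this
   limitation is recorded in the resolution report.
3. **Dropped** with a machine-readable reason otherwise.

Top-decile flagging uses the nearest-rank 90th percentile of a designated
reference cohort's scores as the per-cluster cutoff, with a strict `>` so
ties fall below.

## Association models and meta-analysis

Binary outcomes use logistic regression, the quantitative outcome (eGFR) an
ordinary linear model; covariates are age, sex and ten genetic principal
components.  The exposure is score/10 (so coefficients are per 10 units) or
the top-decile flag.  An optional screening step retains only PCs nominally
associated (p < 0.05) with the outcome in a null model; it is off by default.
Cohort fits that fail (separation, non-convergence, too few cases — fewer
than 10 cases or controls for binary outcomes, fewer than 30 observations
for quantitative) are flagged and excluded from pooling rather than imputed.

Study-level coefficients are pooled with IVW fixed effects: weights
`w_i = 1/se_i^2`, pooled SE `1/sqrt(sum w_i)`, Wald p from the normal
distribution, 95% CI at ±1.96 SE (reporting convention; p-values keep full
precision).  Heterogeneity: Cochran's `Q = sum w_i (b_i - b_pooled)^2` and
`I^2 = max(0, (Q - (k-1))/Q) * 100`, undefined (NaN) for a single study.
Significance is flagged at the Bonferroni-adjusted two-sided level
`alpha / n_tests`, by default 0.05/56 for the 8-outcome × 7-cluster family
(displayed truncated as 0.0008; the untruncated value is used for flagging).

## Synthetic data: what it emulates and what it does not

`generate_summary_stats` plants `Z = V T + noise`: `V` (variants × factors,
non-negative) gives every variant one guaranteed "primary" factor plus extra
memberships with probability chosen so the planted zero fraction equals
`sparsity`; nonzero loadings are uniform(0.7, 1) times `weight_scale`.  `T`
(factors × traits, signed) anchors FI at +1 in every factor — all clusters
raise FI by construction — and assigns the remaining traits signed supports
from a diversified catalog of one- and two-factor combinations, which keeps
the planted trait columns mutually below the |r| = 0.85 pruning threshold
(the real study's trait list is likewise already pruned).  Effect-allele
orientation is randomized per variant (~50% emitted on the non-FI-increasing
allele) so alignment is genuinely exercised; beta = Z·SE with a fixed
SE = 0.01 (only Z = beta/SE matters downstream); p-values are two-sided
normal.

The default fixture SUMSTATS-A (230 variants × 43 traits, 7 factors,
`weight_scale = 8` so member |Z| sits in roughly 4–10, unit noise, seed
20230919) mirrors the real input's dimensions and solution.  Because the
real variants were *ascertained* as FI-associated, the fixture draws the
FI-column noise conditional on the emitted FI p-value passing 5e-5
(truncated normal), so selection retains exactly 230 variants.

`generate_cohort` draws dosages as binomial(2, f) per variant
(Hardy–Weinberg, no LD between panel variants), with the panel effect allele
randomly the FI-increasing allele or its partner.  Binary outcomes follow a
logistic model whose linear predictor is
`intercept + sum_c log(OR10_c)/10 * pPS_c` plus small age/sex/PC effects,
with the intercept calibrated by root-finding so the simulated prevalence
matches the configured baseline.  The pPS entering the outcome model is
computed through the same resolution/scoring engine the analysis stage uses:
the score is the estimand, so generative and analysed quantities coincide by
construction.  Quantitative outcomes use the analogous linear model.

The cohort fixture COHORT-A (n = 50,000, T2D prevalence 0.15) takes its
cluster definitions from the planted structure: each variant goes to its
largest-loading factor only (disjoint clusters, hence mutually independent
scores) with weight `sqrt(planted loading)` — the balanced square-root scale
an ARD factorization of the planted matrix converges to.  Its per-cluster
per-10-unit T2D odds ratios are fixed in the shipped config:
0.72 (preserved insulin secretion), 0.93 (elevated insulin secretion),
1.00 (stressed beta-cell), 1.12 (adiposity), 1.15 (visceral adiposity),
1.22 (lipodystrophy-like insulin resistance), 1.09 (hepatic insulin
resistance).

Not emulated: chromosomal LD structure (the LD reference is an explicit
pairwise r² table), population stratification (PCs are pure noise unless the
confounding switch couples age to the total score), GWAS sample overlap
across traits (noise is independent), imputation uncertainty, and
cohort-specific phenotype harmonization.  Passing tests therefore show that
the machinery is correct under these idealizations, not that the scientific
conclusions transfer to any particular real cohort.  One quantifiable gap:
because each cluster's score is fitted marginally while the outcome depends
on all seven, logistic non-collapsibility attenuates recovered odds ratios
by roughly 1–2% at the shipped effect sizes — well inside the tolerances
used, but visible.

## Problem sizes used in the shipped checks

Desk-scale sizes keep the full suite fast while preserving the statistical
properties being checked: rank recovery uses the full 230 × 86 fixture with
50 restarts; effect recovery the full n = 50,000 cohort; the family-wise
null check uses 200 replicate families of 56 tests over two cohorts of
n = 1,000; coverage checks use n = 3,000 with 100 seeded replicates.

## Known limitations

- Effective K from multiplicative ARD updates depends on the early
  competitive phase; the restart mode is the stabilizer.  Exactly noise-free
  inputs need the `noise_free()` settings.
- Proxy orientation with r²-only LD references is frequency-matched, not
  phase-aware; near-0.5-frequency proxies can be mis-oriented.  A signed-LD
  reference would remove this.
- The IVW pooling assumes fixed effects; between-study heterogeneity is
  reported (I²) but not modelled (no random-effects variant).
- Wald inference throughout; exact or penalized methods for rare outcomes
  are not implemented (fits with too few cases are excluded instead).
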