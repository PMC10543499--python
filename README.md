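# insuclust

Genetic subtypes of hyperinsulinemia: clustering fasting-insulin-associated
variants by their multi-trait association profiles, scoring individuals on
each cluster, and meta-analysing cluster–outcome associations.

Fasting insulin (FI) is an accessible biomarker of the molecular alterations
that precede type 2 diabetes, but elevated FI arises from heterogeneous
mechanisms — some diabetogenic, some not.  `insuclust` implements the
pipeline for dissecting that heterogeneity from GWAS summary statistics:

1. **Input matrix** — select variants with FI association p < 5e-5, align
   every trait Z-score (beta/SE) to the FI-increasing allele, prune traits to
   pairwise |r| < 0.85, and split signed Z into non-negative
   positive/negative column pairs.
2. **Clustering** — Bayesian non-negative matrix factorization `X ≈ W H`
   with automatic relevance determination: half-normal priors on the columns
   of W and rows of H share per-component relevance parameters λ_k with an
   inverse-gamma(a, b) hyperprior, so unused components are pruned and the
   number of clusters K is chosen by the data.  The maximum-posterior
   solution at the modal K over random restarts is selected, and a weight
   cutoff (0.84, or the elbow of the pooled weight distribution) defines
   cluster membership.
3. **Partitioned polygenic scores (pPS)** — per individual and cluster,
   `score = Σ_v w_v × dosage(FI-increasing allele of v)`, with proxy
   substitution at r² ≥ 0.8, allele-frequency safeguards for strand-ambiguous
   variants, and top-decile flagging against a reference cohort.
4. **Association and meta-analysis** — per-cohort logistic (binary outcomes)
   or linear (eGFR) models adjusted for age, sex and 10 principal
   components, reported per 10 score units; cohorts pooled by
   inverse-variance-weighted fixed-effects meta-analysis with Cochran's Q
   and I², and Bonferroni significance for the 8-outcome × 7-cluster family
   (α = 0.05/56, printed 0.0008).

Because the cohorts such studies use are access-restricted, the package
includes a first-class synthetic-data generator (`insuclust.simulate`) that
plants a known factor structure in the summary statistics and known
per-cluster odds ratios in simulated cohorts, so the whole pipeline is
testable without any external download.  See `docs/methods.md` for the
model, the generator's scope, and all numerical choices.

## Worked example

```python
import numpy as np
import insuclust as ic

# 1. planted summary statistics: 230 variants x 43 traits, 7 factors
cfg = ic.SUMSTATS_A()
stats, truth = ic.generate_summary_stats(cfg)

variants = ic.select_variants(stats, "FI")          # p < 5e-5, 230 variants
zmat = ic.align_to_risk_allele(stats, variants, "FI")
zmat = ic.prune_traits(zmat)                        # |r| < 0.85, 43 retained
X = ic.build_nonnegative_matrix(zmat)               # 230 x 86 (pos/neg split)

# 2. ARD bNMF over restarts; modal-K maximum-posterior solution
fits = ic.BayesianNMF(X).fit_restarts(n_restarts=50, seed=1)
solution = ic.select_solution(fits)
print(solution.fit.summary())

# 3. score a simulated cohort on the planted clusters and recover effects
cohort_cfg = ic.COHORT_A()
defs = ic.planted_cluster_definitions(truth)
ld = ic.generate_ld_reference(cohort_cfg, variant_ids=defs.all_variant_ids())
panel, cohort = ic.generate_cohort(cohort_cfg, defs, ld=ld, seed=1)
pps = ic.compute_pps(panel, ic.resolve_variants(defs, panel, ld))

for cluster in ("lipodystrophy_ir", "preserved_insulin_secretion"):
    fit = ic.fit_outcome_model(cohort, pps, cluster, "T2D")
    print(f"{cluster}: OR per 10 units = {np.exp(fit.estimate):.3f}")
```

Output from this session:

```
Bayesian NMF (ARD) fit
  shape:          230 x 86
  k0:             20
  effective K:    7
  ...
lipodystrophy_ir: OR per 10 units = 1.205
preserved_insulin_secretion: OR per 10 units = 0.728
```

The clustering recovers the seven planted factors as the modal effective K,
and the association stage recovers the configured per-10-unit T2D odds
ratios (generative values 1.22 for the lipodystrophy-like
insulin-resistance cluster, 0.72 for the preserved-insulin-secretion
cluster) within sampling error — an estimated OR above 1 means the cluster's
FI-raising alleles also raise T2D risk (diabetogenic hyperinsulinemia),
below 1 the opposite.

A command-line interface mirrors the library
(`insuclust simulate | build-matrix | cluster | score | associate | meta`),
and `insuclust run --config run.yaml` executes the whole pipeline from one
YAML config with deterministic per-stage seeding and a checksummed run
manifest.

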