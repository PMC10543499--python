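# COHORT-A: 50,000 individuals scored on the SUMSTATS-A planted clusters, with
# one binary T2D outcome (baseline prevalence 0.15) whose per-cluster
# per-10-unit odds ratios are the generative ground truth the association
# stage recovers.
n_variants: 230
n_traits: 43
k_true: 7
weight_scale: 8.0
noise_sd: 1.0
sparsity: 0.8
seed: 20230919
maf_range: [0.05, 0.5]
fi_ascertainment: true
n_individuals: 50000
cluster_names:
  - preserved_insulin_secretion
  - elevated_insulin_secretion
  - stressed_beta_cell
  - adiposity_ir
  - visceral_adiposity_ir
  - lipodystrophy_ir
  - hepatic_ir
outcome_specs:
  - name: T2D
    kind: binary
    baseline: 0.15
    effects:
      preserved_insulin_secretion: 0.72
      elevated_insulin_secretion: 0.93
      stressed_beta_cell: 1.00
      adiposity_ir: 1.12
      visceral_adiposity_ir: 1.15
      lipodystrophy_ir: 1.22
      hepatic_ir: 1.09
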