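# SUMSTATS-A: 230 FI-associated variants x 43 traits with 7 planted factors.
# weight_scale 8 puts planted member |Z| in roughly 4-10; noise sd 1 on top.
n_variants: 230
n_traits: 43
k_true: 7
weight_scale: 8.0
noise_sd: 1.0
sparsity: 0.8
seed: 20230919
maf_range: [0.05, 0.5]
fi_ascertainment: true
cluster_names:
  - preserved_insulin_secretion
  - elevated_insulin_secretion
  - stressed_beta_cell
  - adiposity_ir
  - visceral_adiposity_ir
  - lipodystrophy_ir
  - hepatic_ir
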