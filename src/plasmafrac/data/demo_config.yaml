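# Demo configuration: full pipeline on default synthetic data.
seed: 0
stages:
  simulate: true
  fracmetrics: true
  proteomics: true
  catalogues: true
  rna: true
simulate:
  plasma_volume_ml: 2.0
  noise_cv: 0.10
  crude_fractions: [5, 6]
proteomics:
  s0: 0.1
  min_valid_fraction: 0.6666666666666666
  n_permutations: 250
  fdr_alpha: 0.05
catalogues:
  alpha: 0.05
rna:
  n_reps: 4
  gsea_permutations: 1000
  lfc_threshold: 1.0
  alpha: 0.05
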