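# Demo pipeline configuration: a small synthetic community that runs end to
# end in about a minute on one CPU. All values are overridable; see
# docs/methods.md for what each parameter means.
seed: 42
simulate:
  n_genomes: 8
  n_samples_low: 2
  n_samples_high: 2
  n_shotgun_pairs: 2500
  n_amplicon_reads: 600
  substitution_error_rate: 0.005
  genome_divergence: [0.10, 0.35]
seeds:
  cluster_identity: 0.99
  top_k: 8
recruit:
  min_identity: 98.0
  max_matches: 3
assemble:
  k: 31
  min_cov: 3
  min_report_len: 800
evaluate:
  success_identity: 99.0
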