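config_version: 1
kind: phenotype
genotype: col_dL0.5
n_segments: 103
proportions:
  p_normal: 0.50
  p_branched: 0.29
  p_transformed: 0.16
  p_absent: 0.05
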