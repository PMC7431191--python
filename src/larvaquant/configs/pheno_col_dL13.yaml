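config_version: 1
kind: phenotype
genotype: col_dL1.3
n_segments: 190
proportions:
  p_normal: 0.04
  p_branched: 0.06
  p_transformed: 0.852
  p_absent: 0.048
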