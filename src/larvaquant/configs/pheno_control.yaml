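config_version: 1
kind: phenotype
genotype: control
n_segments: 127
proportions:
  p_normal: 0.97
  p_branched: 0.01
  p_transformed: 0.01
  p_absent: 0.01
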