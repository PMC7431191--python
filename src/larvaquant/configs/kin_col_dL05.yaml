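config_version: 1
kind: kinematics
genotype: col_dL0.5
n_larvae: 108
params:
  walking_rate_mean: 1.05
  stride_length_mean: 1.08
  stride_length_sd: 0.26
  stride_duration_mean: 1.15
  stride_duration_sd: 0.177
  heading_sd: 0.15
  fps: 5.0
  duration: 20.0
  pause_prob: 0.0
  pause_duration: 1.0
  spine_length_rest: 4.0
  contraction_amplitude: 0.15
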