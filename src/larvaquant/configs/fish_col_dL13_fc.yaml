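config_version: 1
kind: fish
genotype: col_dL1.3
stage: FC
params:
  n_nuclei: 24
  ratio_mean: 1.10
  ratio_sd: 0.20
  nau_amplitude_mean: 100000.0
  background_level: 20.0
  psf_sigma: 1.5
  noise_model: poisson
  stack_shape: [16, 256, 256]
  n_channels: 2
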