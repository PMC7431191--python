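config_version: 1
kind: fish
genotype: col_dL0.5
stage: PC
params:
  n_nuclei: 18
  ratio_mean: 1.19
  ratio_sd: 0.17
  nau_amplitude_mean: 100000.0
  background_level: 20.0
  psf_sigma: 1.5
  noise_model: poisson
  stack_shape: [16, 256, 256]
  n_channels: 2
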