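# Scaled-down configuration: 6 mice x 4 scans on a 64 x 32 x 128 grid,
# sized so a full simulate->train->evaluate->repeatability pass finishes on
# one CPU core in minutes.
cohort: tiny
training:
  batch_size: 16
  max_epochs: 5
  learning_rate: 0.003
  base_filters: 8
  threshold: 0.5
annotator:
  volume_bias_fraction: 0.14
  volume_bias_sd: 0.04
  boundary_jitter_sigma: 1.0
  seed: 0
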