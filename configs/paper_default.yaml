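# Full-census configuration: 32 mice, 157 scans (49 test-retest pairs) at
# 128 x 64 x 256 voxels, with the full-scale training protocol.  Training at
# this scale is a long CPU run; use tiny.yaml for quick end-to-end passes.
cohort: paper_default
training:
  batch_size: 40
  max_epochs: 120
  learning_rate: 0.001
  base_filters: 16
  threshold: 0.5
annotator:
  volume_bias_fraction: 0.14
  volume_bias_sd: 0.04
  boundary_jitter_sigma: 1.0
  seed: 0
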