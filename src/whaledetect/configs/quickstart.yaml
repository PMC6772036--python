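aerial:
  width_px: 2480
  height_px: 2480
  gsd_m: 0.02
  sea_state: 1
  n_whales: 2
  whale_length_m:
  - 7.0
  - 9.0
  n_duplicate_frames: 2
  distractors: []
  seed: 1
  contrast: 0.15
  include_ms_pan: false
satellite:
  width_px: 320
  height_px: 320
  gsd_m: 0.31
  sea_state: 1
  n_whales: 2
  whale_length_m:
  - 12.0
  - 16.0
  n_duplicate_frames: 1
  distractors: []
  seed: 2
  contrast: 0.15
  include_ms_pan: true
n_aerial: 10
n_satellite: 4
tile_px: 32
stride_px: null
retention_threshold: 0.2
n_folds: 10
fold_unit: frame
eval_fold: 0
train:
  architecture: smallnet
  pretrained: false
  learning_rate: 0.01
  momentum: 0.9
  step_size_epochs: 7
  decay_factor: 0.1
  batch_size: 16
  n_epochs: 24
  sampler: weighted
  input_px: 32
  seed: 1
baselines:
- model: ridge
  alpha: 1.0
  C: 1.0
  kernel: rbf
  seed: 0
- model: c_svc
  alpha: 1.0
  C: 1.0
  kernel: rbf
  seed: 0
water_test_subsample: null
pansharpen: true
seed: 1
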