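# Single source of truth for every default the pipeline uses.
seed: 0
log_level: INFO
spacing_nm: [30.0, 10.0, 10.0]   # (z, y, x); ATUM-style 50/2/2, FIB-style 5/5/5
paths:
  workdir: mito3d_run
  volume: null          # input stack (tiff/h5); null -> produced by simulate
  labels: null          # ground-truth labels, same formats
stages:
  simulate: true
  preprocess: true
  train: true
  predict: true
  connect: true
  evaluate: true
  morph: true
scene:
  shape: [20, 128, 128]
  n_objects: [3, 6]
  object_kinds: [ellipsoid, bent_tube]
  radius_um: [0.06, 0.11]
  tube_length_um: [0.25, 0.45]
  margin_vox: 3
  noise_sigma: 6.0
  slice_jitter: 10.0
preprocess:
  equalize: true
  n_levels: 256
patch:
  shape: [8, 32, 32]
  stride: null          # null = non-overlapping tiling
  augment: true
network:
  preset: tiny          # tiny | default | isotropic
  base_channels: 8      # tiny preset trunk width
  widths: [10, 20, 40, 80]
  aux_weights: [0.15, 0.3]
  lambda_reg: 1.0e-4
train:
  learning_rate: 1.0e-4
  beta1: 0.9
  beta2: 0.999
  eps: 1.0e-8
  batch_size: 2
  epochs: 30
  val_fraction: 0.1
tiles:
  shape: [8, 64, 64]
  overlap: [2, 16, 16]
  tta_variants: 1       # 1 | 8 | 16
  threshold: 0.5
connect:
  iou_threshold: 0.1
  connectivity: 8
  min_voxels: 1500
detection:
  overlap_threshold: 0.70
  overlap: iou
  sweep_grid: [0.65, 0.70, 0.75, 0.80, 0.85]
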