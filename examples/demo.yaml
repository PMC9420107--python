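# Demo-scale pipeline: one small clustered field, ~3 minutes on one CPU.
frame_shape: [64, 64]
structures:
  n_filaments: 3
  n_patches: 2
  n_outlines: 3
  filament_site_density_per_um: 300.0
  patch_site_density_per_um2: 3000.0
  outline_site_density_per_um: 300.0
n_sparse_frames: 1000
n_predict_frames: 80
predict_density: 1.0
summing:
  patch_size: 16
  target_density: 1.9
  n_outputs: 2500
map_cfg:
  upsampling: 4
train_cfg:
  epochs: 10
  batch_size: 8
  learning_rate: 0.0015
  base_filters: 24
  validation_fraction: 0.1
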