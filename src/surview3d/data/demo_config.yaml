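# Desk-scale end-to-end demo: 12 jittered thoracic phantoms, dual- and
# single-view models at channel divisor 8 (128x128 topograms -> 32^3 volumes).
arch: both
out_dir: runs/demo
make_figures: true
phantom:
  n: 12
  seed: 0
  jitter:
    body_semi_axes_mm: 0.1
    lung_semi_axes_mm: 0.1
    lung_centers_mm: 0.05
    spine_radius_mm: 0.1
  base:
    grid_shape: [64, 64, 64]
    spacing_mm: [4.0, 4.0, 4.0]
    body_semi_axes_mm: [80.0, 105.0]
    body_hu: 40.0
    lung_centers_mm: [[0.0, 0.0, -50.0], [0.0, 0.0, 50.0]]
    lung_semi_axes_mm: [[85.0, 45.0, 30.0], [85.0, 45.0, 30.0]]
    lung_hu: -800.0
    spine_center_yx_mm: [55.0, 0.0]
    spine_radius_mm: 12.0
    spine_hu: 700.0
    trachea_radius_mm: 8.0
    trachea_hu: -1000.0
    noise_sigma_hu: 10.0
    seed: 0
geometry:
  source_to_isocenter_mm: 600.0
  source_to_detector_mm: 1100.0
  detector_pixels: [128, 128]
  i0: 1.0
network:
  input_size: 128
  output_size: 32
  channel_divisor: 8
  depth: 6
  gen_entry_size: 2
  seed: 0
train:
  learning_rate: 0.0002
  batch_size: 4
  max_epochs: 60
  checkpoint_every: 10
  patience: 20
  seed: 0
  split: [0.9, 0.1, 2]
evaluation:
  lung_threshold_hu: -320.0
  body_threshold_hu: -500.0
  window: [-1000.0, 1000.0]
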