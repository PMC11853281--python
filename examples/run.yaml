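# Example run configuration for the neomotion CLI.
# Precedence: command-line overrides > this file > built-in defaults.
seed: 1
log_level: INFO

study:            # what `neomotion simulate` renders
  n_subjects: 4
  clips_per_subject: 2
  distance_range_mm: [230, 800]
  scene:
    frame_shape: [120, 160]
    duration_s: 60
    body_axes_px: [45, 65]
    chest_axes_px: [15, 21]
    relief_scale_px: 14
    events:
      rate_per_min: 3.0
      duration_s_range: [1, 5]
      region_px_range: [50, 500]
      amplitude_mm_range: [5, 120]

denoise:          # published operating point; override to experiment
  lower_pct: 3
  upper_pct: 87
  max_diff_mm: 150
  min_region_px: 40

forest:
  n_trees: 100
  max_features: 4

paths:
  dataset_dir: dataset
  model_path: model.joblib
  report_dir: report
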