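# Desk-scale screening run: ~1-2 minutes on one CPU core.
# Full-scale defaults (Adam 1e-4, batch 32, 100 epochs with early stopping)
# live in gwoscreen.pipeline.default_config(); this file overrides the
# budgets so the whole pipeline runs quickly on synthetic data.
seed: 0
data:
  image_side: 64
  n_per_class: 40
  train_fraction: 0.75     # 30 train / 10 test per class
segmenter:
  depth: 2
  base_filters: 8
  learning_rate: 1.0e-3
  epochs: 30
  batch_size: 8
capsnet:
  conv_filters: 32         # desk profile; printed architecture uses 256
  primary_caps_types: 4    # desk profile; printed architecture uses 32
  epochs: 25
  learning_rate: 1.0e-3
  batch_size: 16
gwo:
  enabled: false           # set true to GWO-tune the segmenter first
  n_wolves: 5
  max_iters: 5
  budget_epochs_per_eval: 3
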