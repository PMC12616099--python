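# Minimal end-to-end experiment: a small phantom cohort, two seeds,
# contrastive encoder + ridge head, aggregate MAE with a t-based CI.
phantom:
  grid_shape: [8, 8, 8]
  n_subjects: 40
  seed: 0
encoder:
  in_channels: 2
  embedding_dim: 8
train:
  epochs: 4
  batch_size: 8
  seed: 0
modality_set: mre
n_seeds: 2
output_dir: results/quickstart
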