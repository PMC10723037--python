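data_dir: data
output_dir: ckpt
seed: 1
model:
  num_layers: 2
  hidden_dim: 32
  num_heads: 4
training:
  n_folds: 2
  max_epochs: 12
  patience: 12
  proteins_per_epoch: 20
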