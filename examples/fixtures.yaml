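# generate a synthetic dataset in the standard on-disk layout
output_dir: data
seed: 1
synthetic:
  n_proteins: 20
  length_range: [30, 60]
  embed_dim: 8
  pn_ratio_target: 0.18
  signal_mode: sequence_only
  snr: 3.0
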