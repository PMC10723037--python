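data_dir: data
checkpoint_dir: ckpt
output_dir: pred
seed: 1
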