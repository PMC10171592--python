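# Narrow CPU-friendly architecture for phantom experiments.
# The default widths [64, 128, 256, 512, 512] reproduce the full-size
# networks (34M / 29M parameters) but are impractical to train without a GPU.
net:
  widths: [8, 16, 32, 64, 64]
train:
  batch_size: 16
  learning_rate: 1.0e-3
  weight_decay: 1.0e-4
tversky:
  alpha: 0.7
  beta: 0.3
  gamma: 1.3333333333333333
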