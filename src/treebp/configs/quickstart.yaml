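# Quickstart: a small Tree-3 on the bundled synthetic 10-class task.
seed: 7
arch:
  kind: tree3
  channels: 1
  filters_per_channel: 2
  branches: 4
  height: 16
  width: 16
  slab_rows: 2
  classes: 10
  activation: relu
data:
  kind: synthetic
  train_per_class: 40
  test_per_class: 20
  amplitude: 1.0
  noise_std: 0.3
train:
  lr: 0.05
  momentum: 0.9
  weight_decay: 0.0
  batch_size: 20
  epochs: 30
  engine: reference
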