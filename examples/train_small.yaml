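# Desk-scale training configuration: 64x64 phantoms, 3-branch model.
# The optimizer settings (batch 2, lr 2e-4, decay 0.96 / 300 steps) are the
# full protocol's; epochs and image size are scaled to CPU.
batch_size: 2
epochs: 25
image_size: 64
initial_lr: 0.0002
decay_steps: 300
decay_rate: 0.96
optimizer: adam
seed: 1
augment: true
rotation_range: 15.0
zoom_range: [0.9, 1.1]
shear_range: 8.0
flip_prob: 0.5
model:
  in_channels: 1
  num_levels: 3
  base_channels: 8
  cse_reduction: 2
  dropout_rate: 0.2
  out_channels: 1
  seed: 1
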