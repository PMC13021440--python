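# Optimised compound-loss training profile, shipped as metadata for
# downstream training systems (the training loop itself is out of scope).
loss_weights:
  dice: 0.5
  skeleton_recall: 0.33
  cross_entropy: 0.17
patch_size: [96, 192, 192]
batch_size: 4
max_epochs: 150
patience: 20
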