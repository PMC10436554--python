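# Scaled-down study configuration: finishes on one CPU in ~15 minutes.
# 5 subjects x 80 trials per domain, 25 epochs, batch 16, reduced network
# widths (generator 8 base filters / 3 residual blocks, discriminator
# 32..256 filters with the unchanged 70-sample patch receptive field).
n_subjects: 5
trials_per_domain:
  walking: 80
  running: 80
  writing: 80
sigma_trial: 0.3
seed: 1
locomotion_scaling: global
contact_threshold_n: 50.0
generator:
  base_filters: 8
  n_resnet_blocks: 3
discriminator:
  filters: [32, 64, 128, 256]
training:
  epochs: 25
  batch_size: 16
split: {}
svm: {}
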