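# Full-scale parameters: 17 subjects, trial counts near the original
# cohort (about 628 walking / 963 running / 59 writing per subject),
# 200 epochs with batch 64, full-width networks.  Expect multi-day
# runtimes on a single CPU; intended for reference and for porting the
# configuration to faster hardware.
n_subjects: 17
trials_per_domain:
  walking: 628
  running: 963
  writing: 59
sigma_trial: 0.3
seed: 0
locomotion_scaling: global
contact_threshold_n: 50.0
generator:
  base_filters: 64
  n_resnet_blocks: 9
discriminator:
  filters: [64, 128, 256, 512]
training:
  epochs: 200
  batch_size: 64
split: {}
svm: {}
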