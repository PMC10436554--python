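"""Train a small class-conditioned CycleGAN between walking and running
and translate held-out strides, then overlay original vs generated
curves for one subject.

Deliberately tiny so it finishes in about a minute; expect rough
translations — the full protocol lives in 05_full_experiment.py.
"""

from crossmove.classify import SplitPlan, make_splits
from crossmove.cyclegan import TrainingPlan, train_pair, translate_dataset
from crossmove.networks import DiscriminatorSpec, GeneratorSpec
from crossmove.pipeline import (ExperimentConfig, _scale_locomotion,
                                _wrap_unscaled, plot_overlays,
                                simulate_trials)

config = ExperimentConfig(
    n_subjects=3,
    trials_per_domain={"walking": 40, "running": 40, "writing": 4},
    seed=5,
)
raw = _wrap_unscaled(config, simulate_trials(config))

partitions = {}
for domain in ("walking", "running"):
    split = make_splits(raw[domain], SplitPlan(seed=1))
    train_ids = {t.trial_id for t in split["gan_train"]}
    scaled = _scale_locomotion(raw[domain], "global", train_ids)
    partitions[domain] = {
        "train": [t for t in scaled if t.source_trial_id in train_ids],
        "heldout": [t for t in scaled if t.source_trial_id not in train_ids],
    }

plan = TrainingPlan(epochs=5, batch_size=16, schedule_kind="locomotion_pair",
                    seed=2)
pair = train_pair(partitions["walking"]["train"],
                  partitions["running"]["train"], plan,
                  GeneratorSpec(base_filters=8, n_resnet_blocks=2),
                  DiscriminatorSpec(filters=(16, 32, 64, 128)),
                  progress=True)
print(f"selected checkpoint: epoch {pair.selected_epoch} "
      f"(lowest epoch-mean generator objective)")

generated = translate_dataset(pair.G, partitions["walking"]["heldout"])
print(f"translated {len(generated)} held-out walking strides into "
      f"{generated[0].domain!r}; labels pass through "
      f"(first trial subject={generated[0].subject_id})")

figure = plot_overlays(partitions["running"]["heldout"], generated,
                       subject_id=0, path="/tmp/crossmove_overlay.png")
print(f"overlay written to {figure}: mean +/- SD of real running strides "
      "vs strides generated from walking (subject 0)")
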