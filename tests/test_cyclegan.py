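"""Losses against brute-force oracles; schedule; training-loop contracts."""

import numpy as np
import pytest

from crossmove.cyclegan import (ClassEmbedding, TrainingPlan, adversarial_loss,
                                cycle_loss, generator_lr, identity_loss,
                                load_pair, save_pair, schedule_kind_for,
                                total_objective, train_pair,
                                translate_dataset)
from crossmove.networks import DiscriminatorSpec, GeneratorSpec
from crossmove.preprocess import MovementVector

SMALL_GEN = GeneratorSpec(base_filters=8, n_resnet_blocks=2)
SMALL_DISC = DiscriminatorSpec(filters=(8, 16, 32, 64))


def _toy_trials(domain, n_subjects=3, n_per_subject=6, seed=0):
    """Smooth subject-specific curves in [0, 1] for loop-level tests."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 256)
    trials = []
    for sid in range(n_subjects):
        base = 0.5 + 0.3 * np.sin(2 * np.pi * (2 + sid) * t)
        for i in range(n_per_subject):
            values = np.clip(base + 0.02 * rng.normal(size=256), 0.001, 0.999)
            trials.append(MovementVector(values=values, domain=domain,
                                         subject_id=sid, condition="normal",
                                         source_trial_id=f"{domain}{sid}_{i}"))
    return trials


class TestClassEmbedding:
    def test_one_hot_invariant(self):
        z = ClassEmbedding.from_index(2, 5)
        assert z.index == 2 and z.vector.sum() == 1

    def test_rejects_non_one_hot(self):
        with pytest.raises(ValueError):
            ClassEmbedding(np.array([0.5, 0.5]))


class TestLosses:
    def test_adversarial_saturation_at_perfect_discrimination(self):
        assert adversarial_loss(np.ones(8), np.zeros(8)) == 0.0

    def test_adversarial_at_chance(self):
        value = adversarial_loss(np.full(10, 0.5), np.full(10, 0.5))
        assert value == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_adversarial_matches_elementwise_oracle(self, rng):
        d_real = rng.uniform(0.05, 0.95, size=(4, 7))
        d_fake = rng.uniform(0.05, 0.95, size=(4, 7))
        oracle = (sum(np.log(p) for p in d_real.ravel()) / d_real.size
                  + sum(np.log(1 - p) for p in d_fake.ravel()) / d_fake.size)
        assert adversarial_loss(d_real, d_fake) == pytest.approx(oracle)

    def test_adversarial_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.array([1.2]), np.array([0.5]))

    def test_cycle_perfect_reconstruction_is_zero(self, rng):
        x, y = rng.uniform(size=(2, 256)), rng.uniform(size=(3, 256))
        assert cycle_loss(x, x, y, y) == 0.0

    def test_cycle_constant_offset(self, rng):
        x, y = rng.uniform(size=(2, 256)), rng.uniform(size=(2, 256))
        assert cycle_loss(x, x + 0.01, y, y + 0.01) == pytest.approx(0.02)

    def test_cycle_matches_elementwise_oracle(self, rng):
        x, xr, y, yr = (rng.uniform(size=(3, 16)) for _ in range(4))
        oracle = (sum(abs(u - v) for u, v in zip(xr.ravel(), x.ravel()))
                  / x.size
                  + sum(abs(u - v) for u, v in zip(yr.ravel(), y.ravel()))
                  / y.size)
        assert cycle_loss(x, xr, y, yr) == pytest.approx(oracle)

    def test_identity_for_identity_generators(self, rng):
        x, y = rng.uniform(size=(2, 64)), rng.uniform(size=(2, 64))
        assert identity_loss(y, y, x, x) == 0.0
        assert identity_loss(y, y + 0.05, x, x) == pytest.approx(0.05)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cycle_loss(rng.uniform(size=4), rng.uniform(size=5),
                       rng.uniform(size=4), rng.uniform(size=4))

    def test_total_objective_weighting(self, rng):
        plan = TrainingPlan()
        assert total_objective(0, 0, 0, 0, plan) == 0
        assert total_objective(0, 0, 1, 1, plan) == 15.0
        parts = rng.normal(size=4)
        assert total_objective(*parts, plan) == pytest.approx(
            parts[0] + parts[1] + 10 * parts[2] + 5 * parts[3])

    def test_total_objective_rejects_non_finite(self):
        with pytest.raises(ValueError):
            total_objective(np.inf, 0, 0, 0, TrainingPlan())


class TestSchedule:
    def test_printed_values(self):
        assert generator_lr(10, "writing_pair") == pytest.approx(0.0128)
        assert generator_lr(60, "writing_pair") == pytest.approx(0.0016)
        assert generator_lr(0, "locomotion_pair") == pytest.approx(0.0002)
        assert generator_lr(150, "locomotion_pair") == pytest.approx(0.0001)

    def test_linear_decay_tail(self):
        assert generator_lr(199, "locomotion_pair") == pytest.approx(
            0.0002 * 0.01)
        assert generator_lr(150, "writing_pair") == pytest.approx(0.0008)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            generator_lr(200, "locomotion_pair")
        with pytest.raises(ValueError):
            generator_lr(-1, "writing_pair")

    def test_kind_from_domains(self):
        assert schedule_kind_for("walking", "running") == "locomotion_pair"
        assert schedule_kind_for("running", "writing") == "writing_pair"


class TestTrainingLoop:
    def test_smoke_contract_one_epoch(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=1, batch_size=8, seed=2)
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        out = pair.G(np.stack([t.values for t in a[:2]]), np.eye(3)[[0, 1]])
        assert out.shape == (2, 256)
        assert len(pair.loss_log) == 1

    def test_selected_epoch_is_argmin_of_log(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=3, batch_size=8, seed=3)
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        assert pair.selected_epoch == int(pair.loss_log["total"].idxmin())

    def test_zero_learning_rates_leave_parameters_unchanged(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=1, batch_size=8, seed=4, d_lr=0.0,
                            g_lr_override=0.0)
        from crossmove.networks import build_generator
        seeds = np.random.SeedSequence([4, 17]).generate_state(5)
        fresh = build_generator(SMALL_GEN, 3, seed=int(seeds[0]) % (2 ** 31))
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        for before, after in zip(fresh.get_state(), pair.G.get_state()):
            assert np.array_equal(before, after)

    def test_logged_total_is_weighted_sum_of_components(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=2, batch_size=8, seed=5)
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        log = pair.loss_log
        recomputed = (log.l_gan_G + log.l_gan_F + plan.lambda_cyc * log.l_cyc
                      + plan.lambda_id * log.l_id)
        assert np.allclose(log.total, recomputed, atol=1e-12)

    def test_reproducible_given_seed(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=1, batch_size=8, seed=6)
        p1 = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        p2 = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        for s1, s2 in zip(p1.G.get_state(), p2.G.get_state()):
            assert np.array_equal(s1, s2)

    def test_least_squares_option_trains(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=2, batch_size=8, seed=10,
                            gan_loss="least_squares")
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        assert np.isfinite(pair.loss_log["total"]).all()
        out = pair.G(a[0].values, np.eye(3)[[0]])
        assert np.all((out > 0) & (out < 1))

    def test_last_checkpoint_and_extra_discriminator_steps(self):
        a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
        plan = TrainingPlan(epochs=2, batch_size=8, seed=11,
                            checkpoint="last", d_steps=2)
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        assert pair.selected_epoch == 1  # final epoch, regardless of loss

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            TrainingPlan(gan_loss="wasserstein")
        with pytest.raises(ValueError):
            TrainingPlan(checkpoint="median")
        with pytest.raises(ValueError):
            TrainingPlan(d_steps=0)

    def test_rejects_empty_or_mismatched_classes(self):
        a = _toy_trials("walking")
        plan = TrainingPlan(epochs=1, batch_size=4)
        with pytest.raises(ValueError):
            train_pair(a, [], plan, SMALL_GEN, SMALL_DISC)
        b = _toy_trials("running", n_subjects=2)
        with pytest.raises(ValueError):
            train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)

    def test_identity_dominated_self_translation_approaches_identity(self):
        """With A = B and a large identity weight, training must drive the
        generator toward the identity map (decreasing deviation)."""
        a = _toy_trials("walking", n_per_subject=8)
        b = [MovementVector(values=t.values.copy(), domain="running",
                            subject_id=t.subject_id, condition=t.condition,
                            source_trial_id=t.source_trial_id + "b")
             for t in _toy_trials("walking", n_per_subject=8, seed=1)]
        plan = TrainingPlan(epochs=6, batch_size=8, seed=7, lambda_id=50.0,
                            g_lr_override=2e-3)
        pair = train_pair(a, b, plan, SMALL_GEN, SMALL_DISC)
        log = pair.loss_log["l_id"].to_numpy()
        assert log[-1] < 0.5 * log[0]


@pytest.fixture(scope="module")
def trained():
    a, b = _toy_trials("walking"), _toy_trials("running", seed=1)
    plan = TrainingPlan(epochs=1, batch_size=8, seed=8)
    return train_pair(a, b, plan, SMALL_GEN, SMALL_DISC), a


class TestTranslate:
    def test_counts_labels_and_determinism(self, trained):
        pair, a = trained
        out1 = translate_dataset(pair.G, a)
        out2 = translate_dataset(pair.G, a)
        assert len(out1) == len(a)
        for src, gen1, gen2 in zip(a, out1, out2):
            assert gen1.subject_id == src.subject_id
            assert gen1.condition == src.condition
            assert gen1.domain == "running" and gen1.origin == "generated"
            assert gen1.source_domain == "walking"
            assert np.array_equal(gen1.values, gen2.values)

    def test_unknown_subject_rejected(self, trained):
        pair, a = trained
        alien = MovementVector(values=a[0].values, domain="walking",
                               subject_id=99)
        with pytest.raises(ValueError):
            translate_dataset(pair.G, [alien])

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        pair, a = trained
        save_pair(pair, tmp_path / "ckpt")
        back = load_pair(tmp_path / "ckpt")
        x = np.stack([t.values for t in a[:3]])
        onehot = np.eye(3)[[0, 1, 2]]
        assert np.array_equal(pair.G(x, onehot), back.G(x, onehot))
        assert back.selected_epoch == pair.selected_epoch
        assert back.domain_a == "walking" and back.domain_b == "running"
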