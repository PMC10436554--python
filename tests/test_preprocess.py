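"""Preprocessing contracts: segmentation, normalization, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmove.preprocess import (ContactInterval, DegenerateSegmentError,
                                  DegenerateTrialError, EmptyTrialError,
                                  MovementVector, TrialDiscardedError,
                                  build_stride_pair, detect_ground_contacts,
                                  extract_first_letter,
                                  locomotion_stride_vectors, pair_contacts,
                                  preprocess_writing, savitzky_golay,
                                  scale_unit_interval, time_normalize)
from crossmove.synthetic import (GRAVITY, RawPenRecording,
                                 simulate_walking_recording,
                                 simulate_writing_trial)


class TestDetectGroundContacts:
    def test_all_zero_series_yields_nothing(self):
        assert detect_ground_contacts(np.zeros(100)) == []

    def test_threshold_crossing_interval(self):
        force = np.array([0, 40, 60, 80, 60, 40, 0], dtype=float)
        intervals = detect_ground_contacts(force, threshold=50)
        assert [(c.start, c.end) for c in intervals] == [(2, 5)]

    def test_inclusive_threshold(self):
        force = np.array([0.0, 50.0, 0.0])
        assert [(c.start, c.end)
                for c in detect_ground_contacts(force)] == [(1, 2)]

    def test_boundary_touching_runs_discarded(self):
        force = np.array([80, 80, 0, 60, 60, 0, 90, 90], dtype=float)
        assert [(c.start, c.end)
                for c in detect_ground_contacts(force)] == [(3, 5)]

    def test_matches_simulator_ground_truth(self, population, domain_maps):
        rec = simulate_walking_recording(population[0],
                                         domain_maps["walking"], 1.0,
                                         n_strides=8, seed=5)
        for foot in ("left", "right"):
            detected = detect_ground_contacts(getattr(rec, foot), foot=foot)
            assert [(c.start, c.end) for c in detected] == [
                tuple(iv) for iv in rec.ground_truth_contacts[foot]]

    def test_idempotent_on_reconstruction(self, population, domain_maps):
        rec = simulate_walking_recording(population[1],
                                         domain_maps["walking"], 1.0, 4,
                                         seed=6)
        detected = detect_ground_contacts(rec.left)
        rebuilt = np.zeros_like(rec.left)
        for c in detected:
            rebuilt[c.start:c.end] = rec.left[c.start:c.end]
        again = detect_ground_contacts(rebuilt)
        assert [(c.start, c.end) for c in again] == [
            (c.start, c.end) for c in detected]

    def test_rejects_negative_force(self):
        with pytest.raises(ValueError):
            detect_ground_contacts(np.array([0.0, -1.0, 60.0, 0.0]))


class TestPairing:
    def _iv(self, s, e, foot):
        return ContactInterval(s, e, foot)

    def test_pairs_earliest_following_right(self):
        left = [self._iv(0, 10, "left"), self._iv(20, 30, "left")]
        right = [self._iv(5, 15, "right"), self._iv(25, 35, "right")]
        pairs = pair_contacts(left, right)
        assert [(l.start, r.start) for l, r in pairs] == [(0, 5), (20, 25)]

    def test_missing_partner_drops_exactly_one_pair(self):
        left = [self._iv(0, 10, "left"), self._iv(20, 30, "left"),
                self._iv(40, 50, "left")]
        right = [self._iv(5, 15, "right"), self._iv(25, 35, "right"),
                 self._iv(45, 55, "right")]
        full = pair_contacts(left, right)
        dropped = pair_contacts(left[:1] + left[2:], right)
        assert len(full) - len(dropped) == 1
        assert len(dropped) <= min(2, len(right))

    @given(st.lists(st.integers(0, 500), min_size=0, max_size=12),
           st.lists(st.integers(0, 500), min_size=0, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_pair_count_bounded(self, lstarts, rstarts):
        left = [self._iv(s, s + 1, "left") for s in sorted(set(lstarts))]
        right = [self._iv(s, s + 1, "right") for s in sorted(set(rstarts))]
        pairs = pair_contacts(left, right)
        assert len(pairs) <= min(len(left), len(right))
        for l, r in pairs:
            assert r.start > l.start


class TestTimeNormalize:
    def test_constant_stays_constant(self):
        out = time_normalize(np.full(37, 3.5), 128)
        assert out.shape == (128,)
        assert np.allclose(out, 3.5)

    def test_identity_when_already_target_length(self, rng):
        seg = rng.uniform(size=128)
        assert np.allclose(time_normalize(seg, 128), seg, atol=1e-9)

    def test_linear_ramp_stays_linear(self):
        ramp = np.linspace(0.0, 1.0, 53)
        out = time_normalize(ramp, 128)
        assert np.allclose(out, np.linspace(0.0, 1.0, 128), atol=1e-12)

    def test_endpoints_preserved(self, rng):
        seg = rng.uniform(size=19)
        out = time_normalize(seg, 256)
        assert out[0] == seg[0] and out[-1] == seg[-1]

    def test_degenerate_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            time_normalize(np.array([1.0]), 128)


class TestStridePair:
    def test_length_and_left_first_layout(self, rng):
        left = 700 * np.concatenate([[0], rng.uniform(0.5, 1, 50), [0]])
        right = np.zeros(60)
        vec = build_stride_pair(left, right, body_mass=70.0)
        assert vec.shape == (256,)
        assert vec[128:].max() == 0 and vec[:128].max() > 0

    def test_peak_is_body_weight_normalized(self, population, noiseless_maps):
        subject = population[0]
        rec = simulate_walking_recording(subject, noiseless_maps["walking"],
                                         1.0, 1, seed=0)
        (a, b), = rec.ground_truth_contacts["left"]
        (c, d), = rec.ground_truth_contacts["right"]
        vec = build_stride_pair(rec.left[a:b], rec.right[c:d],
                                subject.body_mass)
        expected_peak = rec.left[a:b].max() / (subject.body_mass * GRAVITY)
        # resampling to 128 points can shift the sampled peak slightly
        assert vec[:128].max() == pytest.approx(expected_peak, rel=5e-3)


class TestScaling:
    def test_per_trial_affine(self):
        assert np.allclose(scale_unit_interval(np.array([0.0, 5.0, 10.0])),
                           [0.0, 0.5, 1.0])

    def test_per_trial_hits_bounds(self, rng):
        out = scale_unit_interval(rng.normal(size=40))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_global_mode_maps_training_stats(self):
        a, b = 2.0, 6.0
        out = scale_unit_interval(np.array([a, (a + b) / 2, b, 8.0]),
                                  mode="global", global_min=a, global_max=b)
        assert np.allclose(out, [0.0, 0.5, 1.0, 1.0])  # clipped above

    def test_constant_trial_rejected(self):
        with pytest.raises(DegenerateTrialError):
            scale_unit_interval(np.ones(10))


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        assert np.allclose(savitzky_golay(np.full(40, 2.0)), 2.0)

    def test_linear_ramp_unchanged(self):
        ramp = np.linspace(0, 5, 60)
        assert np.allclose(savitzky_golay(ramp), ramp, atol=1e-9)

    def test_order1_equals_centered_moving_average(self, rng):
        """For polynomial order 1 and a symmetric window the least-squares
        fit value at the window centre is the window mean."""
        series = rng.normal(size=200)
        out = savitzky_golay(series, window=13, polyorder=1)
        expected = np.convolve(series, np.ones(13) / 13, mode="valid")
        assert np.allclose(out[6:-6], expected, atol=1e-10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(50), window=12)
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(5), window=13)


class TestFirstLetter:
    def test_length_without_connected_e(self, population, domain_maps):
        rec = simulate_writing_trial(population[0], domain_maps["writing"],
                                     "normal", seed=1, attach_e=False)
        letter = extract_first_letter(rec)
        nonzero = np.flatnonzero(rec.pressure > 0)
        assert len(letter) == rec.ground_truth_letter_end - nonzero[0]
        assert np.array_equal(letter,
                              rec.pressure[nonzero[0]:
                                           rec.ground_truth_letter_end])

    @pytest.mark.parametrize("instruction", ["normal", "bigger", "faster"])
    def test_cut_matches_ground_truth_valley(self, population, domain_maps,
                                             instruction):
        rec = simulate_writing_trial(population[1], domain_maps["writing"],
                                     instruction, seed=2, attach_e=True)
        letter = extract_first_letter(rec)
        start = np.flatnonzero(rec.pressure > 0)[0]
        assert start + len(letter) == rec.ground_truth_letter_end

    def test_broken_letter_discarded(self):
        pressure = np.zeros(400)
        pressure[50:120] = 500.0   # two strokes only, then pen up
        pressure[60:70] = 900.0
        pressure[200:260] = 600.0  # rest of the letter after a pen lift
        rec = RawPenRecording(pressure=pressure, condition="normal",
                              ground_truth_letter_end=260)
        with pytest.raises(TrialDiscardedError):
            extract_first_letter(rec)

    def test_empty_recording_rejected(self):
        rec = RawPenRecording(pressure=np.zeros(100), condition="normal",
                              ground_truth_letter_end=0)
        with pytest.raises(EmptyTrialError):
            extract_first_letter(rec)


class TestWritingPipeline:
    def test_output_contract(self, population, domain_maps):
        rec = simulate_writing_trial(population[2], domain_maps["writing"],
                                     "slower", seed=3, attach_e=True)
        mv = preprocess_writing(rec, subject_id=2, trial_id="w0")
        assert mv.values.shape == (256,)
        assert mv.values.min() == 0.0 and mv.values.max() == 1.0
        assert mv.domain == "writing" and mv.condition == "slower"

    def test_zero_noise_trials_identical(self, population, noiseless_maps):
        mvs = [preprocess_writing(simulate_writing_trial(
            population[0], noiseless_maps["writing"], "normal", seed=s,
            attach_e=True)) for s in (1, 2)]
        assert np.array_equal(mvs[0].values, mvs[1].values)

    def test_filtering_never_splits_pen_down_runs(self, population,
                                                  domain_maps):
        from crossmove.preprocess import savitzky_golay

        def runs(mask):
            return int(np.count_nonzero(np.diff(
                np.concatenate([[0], mask.astype(int), [0]])) == 1))

        for seed in range(5):
            rec = simulate_writing_trial(population[seed % len(population)],
                                         domain_maps["writing"], "normal",
                                         seed=seed, attach_e=bool(seed % 2))
            raw_mask = rec.pressure > 0
            filtered = savitzky_golay(rec.pressure)
            filtered = np.where(raw_mask, np.clip(filtered, 0, None), 0.0)
            assert runs(filtered > 0) <= runs(raw_mask)


class TestMovementVectorInvariants:
    def test_locomotion_vectors_satisfy_contract(self, population,
                                                 domain_maps):
        rec = simulate_walking_recording(population[0],
                                         domain_maps["walking"], 1.0, 6,
                                         seed=4)
        raw_vectors = locomotion_stride_vectors(rec)
        assert len(raw_vectors) == 6
        for vec in raw_vectors:
            mv = MovementVector(values=scale_unit_interval(vec),
                                domain="walking", subject_id=0)
            assert mv.values.shape == (256,)

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            MovementVector(values=np.full(256, 1.5), domain="walking")
        with pytest.raises(ValueError):
            MovementVector(values=np.zeros(255), domain="walking")
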