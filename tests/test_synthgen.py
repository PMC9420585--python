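"""Simulator correctness: beat geometry, truth identifiability, determinism."""

import numpy as np
import pytest

from pulseseg.sequences import BACKGROUND, DIASTOLE, SYSTOLE
from pulseseg.synthgen import (
    DEFAULT_COUNTS,
    FLAT_TOP_TYPES,
    PULSE_TYPES,
    BeatParams,
    NoiseParams,
    generate_dataset,
    generate_record,
    make_beat,
    notch_prominence,
    scaled_counts,
    type_preset,
)


class TestMakeBeat:
    def test_two_gaussian_beat_has_single_interior_valley(self):
        params = BeatParams(0.8, (1.0, 0.0, 0.05), (0.15, 0.3, 0.68), (0.05, 0.06, 0.145))
        waveform, _ = make_beat(params, fs=720.0)
        lo = int(params.centers[0] * 0.8 * 720)
        hi = int(params.centers[2] * 0.8 * 720)
        seg = waveform[lo : hi + 1]
        minima = [
            i for i in range(1, seg.size - 1) if seg[i] <= seg[i - 1] and seg[i] < seg[i + 1]
        ]
        assert len(minima) == 1

    def test_amplitude_scaling_is_linear_and_keeps_notch(self):
        params = type_preset("normal")
        wf1, n1 = make_beat(params, fs=720.0)
        doubled = BeatParams(
            params.period_s, tuple(2 * a for a in params.amps), params.centers, params.widths
        )
        wf2, n2 = make_beat(doubled, fs=720.0)
        assert n1 == n2
        np.testing.assert_allclose(wf2, 2 * wf1, rtol=1e-12)

    @pytest.mark.parametrize("pulse_type", PULSE_TYPES)
    def test_notch_matches_exhaustive_sample_argmin(self, pulse_type):
        """The stored notch is the brute-force argmin between the tidal and
        dicrotic centers of the sampled waveform."""
        params = type_preset(pulse_type, period_s=0.8)
        waveform, notch = make_beat(params, fs=720.0)
        lo = int(np.ceil(params.centers[1] * 0.8 * 720))
        hi = int(params.centers[2] * 0.8 * 720)
        assert notch == lo + int(np.argmin(waveform[lo : hi + 1]))

    @pytest.mark.parametrize(
        "amps,centers,widths",
        [
            ((0.5, 0.6, 0.1), (0.15, 0.3, 0.6), (0.05, 0.06, 0.1)),  # main not dominant
            ((1.0, 0.4, 0.01), (0.15, 0.3, 0.6), (0.05, 0.06, 0.1)),  # dicrotic too weak
            ((1.0, 0.4, 0.2), (0.3, 0.15, 0.6), (0.05, 0.06, 0.1)),  # centers unordered
            ((1.0, 0.4, 0.2), (0.15, 0.3, 0.6), (0.05, -0.06, 0.1)),  # negative width
            ((1.0, np.nan, 0.2), (0.15, 0.3, 0.6), (0.05, 0.06, 0.1)),  # non-finite
        ],
    )
    def test_invalid_beat_params_rejected(self, amps, centers, widths):
        with pytest.raises(ValueError):
            BeatParams(0.8, amps, centers, widths)


class TestGenerateRecord:
    def test_same_seed_identical_output(self):
        r1, t1, l1 = generate_record("slippery", seed=7)
        r2, t2, l2 = generate_record("slippery", seed=7)
        assert np.array_equal(r1.samples, r2.samples)
        assert t1 == t2
        assert np.array_equal(l1.classes, l2.classes)

    @pytest.mark.parametrize("pulse_type", PULSE_TYPES)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noiseless_notch_is_window_argmin(self, pulse_type, seed):
        """With zero noise an independent exhaustive argmin over the central
        60% of each beat reproduces every stored notch exactly."""
        rec, truths, _ = generate_record(pulse_type, noise=NoiseParams.none(), seed=seed)
        assert truths
        for t in truths:
            period = t.next_onset - t.onset
            a = t.onset + int(round(0.2 * period))
            b = t.next_onset - int(round(0.2 * period))
            assert a + int(np.argmin(rec.samples[a:b])) == t.notch

    def test_default_record_shape_and_beat_count(self):
        rec, truths, labels = generate_record("normal", n_samples=2160, fs=720.0, hr_bpm=75)
        assert len(rec) == 2160 and len(labels) == 2160
        assert 2 <= len(truths) <= 4

    def test_labels_consistent_with_truths_and_alternating(self):
        for pulse_type in PULSE_TYPES:
            rec, truths, labels = generate_record(pulse_type, seed=5)
            labels.validate_alternation()
            classes = labels.classes
            for t in truths:
                assert (classes[t.onset : t.notch] == SYSTOLE).all()
                assert (classes[t.notch : t.next_onset] == DIASTOLE).all()
            assert (classes[: truths[0].onset] == BACKGROUND).all()
            assert (classes[truths[-1].next_onset :] == BACKGROUND).all()

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown pulse type"):
            generate_record("bounding", seed=0)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            generate_record("normal", n_samples=100, seed=0)


class TestPresets:
    def test_flat_top_presets_have_weak_merged_morphology(self):
        """String/fine variants: weak dicrotic wave close to the main complex
        and a shallow notch valley (<= 20% of main-wave amplitude)."""
        for pulse_type in FLAT_TOP_TYPES:
            p = type_preset(pulse_type)
            assert p.amps[2] / p.amps[0] <= 0.15
            assert abs(p.centers[1] - p.centers[0]) <= 0.1
            assert notch_prominence(p) <= 0.20

    def test_non_flat_presets_keep_clear_notch(self):
        for pulse_type in set(PULSE_TYPES) - set(FLAT_TOP_TYPES):
            assert notch_prominence(type_preset(pulse_type)) > 0.15


class TestGenerateDataset:
    def test_reference_composition_and_scaling(self):
        assert sum(DEFAULT_COUNTS.values()) == 1400
        scaled = scaled_counts(0.1)
        assert sum(scaled.values()) == 140
        assert scaled == {
            "normal": 12, "slippery": 10, "fine_slippery": 36, "string_slippery": 10,
            "string": 10, "fine": 10, "fine_string": 52,
        }

    def test_requested_counts_and_distinct_seeds(self):
        data = generate_dataset({"normal": 3, "string": 2}, seed=9)
        types = [r.pulse_type for r, _, _ in data]
        assert types == ["normal"] * 3 + ["string"] * 2
        ids = [r.record_id for r, _, _ in data]
        assert len(set(ids)) == 5
        # distinct derived seeds -> distinct waveforms
        assert not np.array_equal(data[0][0].samples, data[1][0].samples)

    def test_pure_function_of_counts_and_seed(self):
        d1 = generate_dataset({"fine": 2}, seed=3)
        d2 = generate_dataset({"fine": 2}, seed=3)
        for (r1, t1, l1), (r2, t2, l2) in zip(d1, d2):
            assert np.array_equal(r1.samples, r2.samples) and t1 == t2

    def test_empty_counts_give_empty_dataset(self):
        assert generate_dataset({t: 0 for t in PULSE_TYPES}, seed=0) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset({"normal": -1}, seed=0)
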