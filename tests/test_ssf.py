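"""Slope-sum-function transform, onset detection, and notch location."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseseg.metrics import per_sample_accuracy
from pulseseg.ssf import (
    SSFConfig,
    detect_notch,
    detect_onsets,
    ssf_segment,
    ssf_transform,
)
from pulseseg.synthgen import (
    BeatParams,
    NoiseParams,
    PulseRecord,
    generate_record,
    make_beat,
    type_preset,
)

FS = 720.0
CFG = SSFConfig()


def naive_ssf(x, w):
    """O(n*w) double-loop reference implementation."""
    d = np.concatenate(([0.0], np.maximum(np.diff(x), 0.0)))
    out = np.zeros_like(np.asarray(x, dtype=float))
    for k in range(len(x)):
        out[k] = d[max(0, k - w + 1) : k + 1].sum()
    return out


class TestTransform:
    def test_monotone_ramp_closed_form(self):
        d, w = 0.5, 10
        x = d * np.arange(100)
        ssf = ssf_transform(x, w)
        np.testing.assert_allclose(ssf[w:], w * d, rtol=1e-12)

    def test_decreasing_signal_gives_zero(self):
        x = -np.arange(50, dtype=float)
        assert not ssf_transform(x, 8).any()

    @given(seed=st.integers(0, 1000), w=st.integers(1, 200))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_double_loop(self, seed, w):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.standard_normal(500))
        np.testing.assert_allclose(ssf_transform(x, w), naive_ssf(x, w), atol=1e-9)

    def test_matches_naive_on_long_pulse_record(self):
        rec, _, _ = generate_record("slippery", n_samples=5000, seed=4)
        w = CFG.window_samples(FS)
        np.testing.assert_allclose(
            ssf_transform(rec.samples, w), naive_ssf(rec.samples, w), atol=1e-9
        )

    def test_peak_sits_between_onset_and_systolic_peak(self):
        params = type_preset("normal")
        beat, _ = make_beat(params, FS)
        w = CFG.window_samples(FS)
        ssf = ssf_transform(beat, w)
        assert 0 < int(np.argmax(ssf)) <= int(np.argmax(beat)) + 1

    def test_window_bounds_enforced(self):
        with pytest.raises(ValueError):
            ssf_transform(np.zeros(10), 0)
        with pytest.raises(ValueError):
            ssf_transform(np.zeros(10), 10)


class TestOnsets:
    def test_flat_signal_has_no_onsets(self):
        assert detect_onsets(np.zeros(2000), CFG, FS) == []

    @pytest.mark.parametrize("pulse_type", ["normal", "slippery", "string", "fine"])
    def test_noiseless_onsets_within_20ms_of_truth(self, pulse_type):
        hits = total = 0
        for seed in range(5):
            rec, truths, _ = generate_record(
                pulse_type, noise=NoiseParams.none(), seed=seed
            )
            ssf = ssf_transform(rec.samples, CFG.window_samples(FS))
            onsets = detect_onsets(ssf, CFG, FS)
            for t in truths:
                total += 1
                hits += min(
                    (abs(o - t.onset) for o in onsets), default=np.inf
                ) <= 0.02 * FS
        assert hits / total >= 0.95

    def test_amplitude_scale_invariance(self, noiseless_record):
        rec, _, _ = noiseless_record
        w = CFG.window_samples(FS)
        a = detect_onsets(ssf_transform(rec.samples, w), CFG, FS)
        b = detect_onsets(ssf_transform(3.0 * rec.samples, w), CFG, FS)
        assert a == b

    def test_time_shift_equivariance(self, noiseless_record):
        rec, _, _ = noiseless_record
        w = CFG.window_samples(FS)
        shift = 180
        shifted = np.concatenate([np.zeros(shift), rec.samples[:-shift]])
        a = detect_onsets(ssf_transform(rec.samples, w), CFG, FS)
        b = detect_onsets(ssf_transform(shifted, w), CFG, FS)
        trimmed = [o for o in a if o + shift < len(rec.samples) - w]
        assert b[: len(trimmed)] == [o + shift for o in trimmed]

    def test_onsets_strictly_increasing(self, noiseless_record):
        rec, _, _ = noiseless_record
        onsets = detect_onsets(
            ssf_transform(rec.samples, CFG.window_samples(FS)), CFG, FS
        )
        assert all(b > a for a, b in zip(onsets, onsets[1:]))


class TestNotch:
    def test_normal_beat_notch_within_20ms(self, noiseless_record):
        rec, truths, _ = noiseless_record
        for t in truths:
            notch, fell_back = detect_notch(
                rec.samples, (t.onset, t.next_onset), CFG, FS
            )
            assert not fell_back
            assert abs(notch - t.notch) <= 0.02 * FS

    def test_barely_there_dicrotic_wave_falls_back_to_inflection(self):
        params = BeatParams(0.8, (1.0, 0.9, 0.05), (0.16, 0.24, 0.70), (0.065, 0.07, 0.13))
        beat, _ = make_beat(params, FS)
        # two concatenated beats give one complete (onset, next_onset) pair
        x = np.concatenate([beat, beat])
        notch, fell_back = detect_notch(x, (0, beat.size), CFG, FS)
        assert notch is not None and 0 < notch < beat.size

    def test_degenerate_window_flagged(self):
        x = np.zeros(2000)
        notch, fell_back = detect_notch(x, (0, 100), CFG, FS)
        assert notch is None and fell_back


class TestSegment:
    def test_noiseless_record_segmented_accurately(self, noiseless_record):
        rec, _, labels = noiseless_record
        result = ssf_segment(rec, CFG)
        assert per_sample_accuracy(result.classes, labels.classes) >= 0.95

    def test_empty_onsets_give_all_background(self):
        rec = PulseRecord(np.zeros(2160), fs=FS)
        result = ssf_segment(rec, CFG)
        assert not result.classes.any() and result.segments == []

    def test_reversed_record_does_not_crash(self, noiseless_record):
        rec, _, _ = noiseless_record
        reversed_rec = PulseRecord(rec.samples[::-1].copy(), fs=FS)
        result = ssf_segment(reversed_rec, CFG)
        assert len(result.classes) == len(rec)
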