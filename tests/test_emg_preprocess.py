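"""EMG conditioning: filters, segmentation, normalization, muscle metrics."""

import numpy as np
import pytest

from synergypipe.core import CycleTensor, EmgRecording, GaitCycles
from synergypipe import emg_preprocess as prep
from synergypipe.synthetic_data import SyntheticConfig, generate_emg

FS = 2000.0


def recording(x):
    x = np.atleast_2d(x).T if np.ndim(x) == 1 else x
    labels = tuple(f"CH{i + 1}" for i in range(x.shape[1]))
    return EmgRecording(x, FS, labels)


def sine(freq, duration=2.0):
    t = np.arange(int(FS * duration)) / FS
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_dc_is_rejected(self):
        out = prep.bandpass_emg(recording(np.full(4000, 3.0)))
        assert np.abs(out.samples[1000:3000].mean()) < 1e-6

    def test_passband_sine_preserved(self):
        out = prep.bandpass_emg(recording(sine(100.0)))
        assert np.abs(out.samples[1000:3000, 0]).max() == pytest.approx(1.0, rel=0.02)

    def test_subband_sine_attenuated(self):
        out = prep.bandpass_emg(recording(sine(1.0)))
        assert np.abs(out.samples[1000:3000, 0]).max() < 0.2

    def test_invalid_band_edges_raise(self):
        with pytest.raises(ValueError):
            prep.bandpass_emg(recording(sine(100.0)), lo=10, hi=1500)


class TestEnvelope:
    def test_zero_in_zero_out(self):
        out = prep.envelope(recording(np.zeros(4000)))
        np.testing.assert_allclose(out.samples, 0.0)

    def test_square_wave_envelope_near_rectified_mean(self):
        x = np.sign(sine(200.0))
        out = prep.envelope(recording(x))
        assert out.samples[1000:3000, 0].mean() == pytest.approx(1.0, rel=0.02)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        e1 = prep.envelope(recording(x)).samples
        e2 = prep.envelope(recording(3.5 * x)).samples
        np.testing.assert_allclose(e2, 3.5 * e1, atol=1e-10)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(1)
        out = prep.envelope(recording(rng.normal(size=4000)))
        assert np.all(out.samples >= 0)

    def test_clean_synthetic_envelope_passes_through_faithfully(self, clean_config):
        # The 10 Hz low-pass should leave a burst-envelope signal nearly
        # unchanged (the bursts live well below 10 Hz).
        rec, _ = generate_emg(clean_config, seed=2)
        env = prep.envelope(rec)
        num = np.linalg.norm(env.samples - rec.samples)
        den = np.linalg.norm(rec.samples)
        assert num / den < 0.05


class TestSegmentAndNormalize:
    def test_fencepost_21_strikes_20_cycles(self):
        rng = np.random.default_rng(0)
        env = recording(np.abs(rng.normal(size=(40000, 3))))
        strikes = np.arange(21) * 1500 + 500
        tensor = prep.segment_and_normalize(env, GaitCycles(strikes, FS))
        assert tensor.n_cycles == 20
        assert tensor.envelopes.shape == (20, 200, 3)

    def test_clean_synthetic_blocks_match_generator_truth(self, clean_dataset, clean_config):
        rec, truth = clean_dataset
        cycles = GaitCycles(truth.strike_samples_true, rec.fs)
        tensor = prep.segment_and_normalize(rec, cycles)
        want = truth.envelope_concatenated
        got = tensor.concatenated
        err = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert err < 0.02

    def test_empty_strikes_raise(self):
        env = recording(np.abs(np.random.default_rng(0).normal(size=(4000, 2))))
        with pytest.raises(ValueError):
            prep.segment_and_normalize(env, GaitCycles([], FS))

    def test_out_of_bounds_strikes_raise(self):
        env = recording(np.abs(np.random.default_rng(0).normal(size=(4000, 2))))
        with pytest.raises(ValueError):
            prep.segment_and_normalize(env, GaitCycles([1000, 5000], FS))


class TestSelectConsecutiveCycles:
    @pytest.mark.parametrize(
        "available,n,start,expect",
        [(25, 20, 0, range(0, 20)), (20, 20, 0, range(0, 20)), (25, 20, 3, range(3, 23))],
    )
    def test_selects_requested_block(self, available, n, start, expect):
        env = np.arange(available)[:, None, None] * np.ones((1, 200, 2))
        tensor = CycleTensor(env, ("A", "B"))
        out = prep.select_consecutive_cycles(tensor, n, start)
        np.testing.assert_array_equal(out.envelopes[:, 0, 0], list(expect))

    def test_too_few_cycles_raise(self):
        tensor = CycleTensor(np.ones((10, 200, 2)), ("A", "B"))
        with pytest.raises(ValueError):
            prep.select_consecutive_cycles(tensor, 20)


class TestAmplitudeNormalize:
    def test_each_muscle_attains_unit_max(self):
        rng = np.random.default_rng(0)
        tensor = CycleTensor(5 * rng.random((4, 200, 3)), ("A", "B", "C"))
        out = prep.amplitude_normalize(tensor)
        np.testing.assert_allclose(out.concatenated.max(axis=1), 1.0)
        assert np.all(out.concatenated >= 0)
        assert np.all(out.concatenated <= 1)

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(1)
        tensor = prep.amplitude_normalize(
            CycleTensor(rng.random((4, 200, 2)), ("A", "B"))
        )
        again = prep.amplitude_normalize(tensor)
        np.testing.assert_allclose(again.envelopes, tensor.envelopes)

    def test_divisors_recorded(self):
        env = np.ones((2, 200, 2))
        env[:, :, 1] *= 4.0
        out = prep.amplitude_normalize(CycleTensor(env, ("A", "B")))
        np.testing.assert_allclose(out.normalization, [1.0, 4.0])

    def test_zero_channel_error_names_channel(self):
        env = np.ones((2, 200, 2))
        env[:, :, 1] = 0.0
        with pytest.raises(ValueError, match="B"):
            prep.amplitude_normalize(CycleTensor(env, ("A", "B")))

    def test_conditions_normalized_independently(self):
        rng = np.random.default_rng(2)
        base = rng.random((4, 200, 2))
        a = prep.amplitude_normalize(CycleTensor(base, ("A", "B")))
        b = prep.amplitude_normalize(CycleTensor(2.7 * base, ("A", "B")))
        np.testing.assert_allclose(a.concatenated.max(axis=1), 1.0)
        np.testing.assert_allclose(b.concatenated.max(axis=1), 1.0)


class TestMuscleMetrics:
    def _tensor(self, scale=1.0):
        rng = np.random.default_rng(3)
        return CycleTensor(scale * (rng.random((5, 200, 3)) + 0.1), ("A", "B", "C"))

    def test_self_comparison_is_100_percent(self):
        t = self._tensor()
        m = prep.muscle_metrics(t, t)
        np.testing.assert_allclose(m.peak_pct_of_reference, 100.0)
        np.testing.assert_allclose(m.integrated_pct_of_reference, 100.0)

    def test_uniform_scaling_reflected_in_both_ratios(self):
        ref = self._tensor()
        cur = self._tensor(scale=1.5)
        m = prep.muscle_metrics(cur, ref)
        np.testing.assert_allclose(m.peak_pct_of_reference, 150.0, rtol=1e-9)
        np.testing.assert_allclose(m.integrated_pct_of_reference, 150.0, rtol=1e-9)

    def test_constant_envelope_integrates_to_its_level(self):
        # A constant curve c, normalized by a reference of mean amplitude 1,
        # integrates to c over the normalized cycle.
        ref = CycleTensor(np.ones((3, 200, 1)), ("A",))
        cur = CycleTensor(np.full((3, 200, 1), 2.5), ("A",))
        m = prep.muscle_metrics(cur, ref)
        assert m.integrated_emg[0] == pytest.approx(2.5)
        assert m.peak_emg[0] == pytest.approx(2.5)

    def test_zero_reference_raises(self):
        ref = CycleTensor(np.zeros((3, 200, 1)), ("A",))
        cur = CycleTensor(np.ones((3, 200, 1)), ("A",))
        with pytest.raises(ValueError):
            prep.muscle_metrics(cur, ref)

    def test_mismatched_labels_raise(self):
        a = CycleTensor(np.ones((3, 200, 1)), ("A",))
        b = CycleTensor(np.ones((3, 200, 1)), ("B",))
        with pytest.raises(ValueError):
            prep.muscle_metrics(a, b)


def test_preprocessing_scale_invariance():
    """Scaling raw input by c>0 leaves the normalized matrix unchanged."""
    rng = np.random.default_rng(4)
    raw = rng.normal(size=(40000, 3))
    strikes = GaitCycles(np.arange(21) * 1500 + 500, FS)

    def run(x):
        rec = EmgRecording(x, FS, ("A", "B", "C"))
        env = prep.envelope(prep.bandpass_emg(rec))
        t = prep.segment_and_normalize(env, strikes)
        return prep.amplitude_normalize(t).concatenated

    np.testing.assert_allclose(run(raw), run(7.3 * raw), atol=1e-9)
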