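import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dft_magnitudes
from ssvepkit.data import FeatureMatrix, Recording, Segment, Trial
from ssvepkit.preprocessing import (
    bandpass_filter,
    extract_fft_features,
    n_windows,
    normalize_features,
    notch_filter,
    sliding_windows,
)


def sinusoid(freq, seconds=4.0, rate=1000.0, n_ch=2):
    t = np.arange(int(seconds * rate)) / rate
    return Recording(np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_ch)), rate)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = bandpass_filter(sinusoid(20.0), 4, 40)
        core = rec.samples[500:-500]
        assert abs(core.max() - 1.0) < 0.01
        assert abs(rms(core) - 1 / np.sqrt(2)) < 0.01 * rms(core)

    def test_out_of_band_tone_attenuated(self):
        rec = bandpass_filter(sinusoid(60.0), 4, 40)
        assert rms(rec.samples[500:-500]) < 0.05 * rms(sinusoid(60.0).samples)

    def test_zero_in_zero_out(self):
        rec = bandpass_filter(Recording(np.zeros((3000, 3)), 1000.0), 4, 40)
        assert np.all(rec.samples == 0.0)

    @pytest.mark.parametrize("low,high", [(0.0, 40.0), (40.0, 4.0), (4.0, 600.0)])
    def test_invalid_band_edges(self, low, high):
        with pytest.raises(ValueError):
            bandpass_filter(sinusoid(20.0), low, high)

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(Recording(np.zeros((10, 2)), 1000.0), 4, 40)


class TestNotch:
    def test_mains_tone_removed(self):
        rec = notch_filter(sinusoid(60.0), 60.0)
        assert rms(rec.samples[500:-500]) < 0.05 * (1 / np.sqrt(2))

    def test_distant_tone_preserved(self):
        rec = notch_filter(sinusoid(13.0), 60.0)
        assert abs(rms(rec.samples[500:-500]) - 1 / np.sqrt(2)) < 0.01 / np.sqrt(2)

    def test_zero_in_zero_out(self):
        rec = notch_filter(Recording(np.zeros((3000, 2)), 1000.0), 60.0)
        assert np.all(rec.samples == 0.0)

    def test_frequency_beyond_nyquist(self):
        with pytest.raises(ValueError):
            notch_filter(sinusoid(20.0), 600.0)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "shift_ms,expected",
        [(60, 50), (30, 100), (20, 150), (15, 200), (12, 250), (10, 300)],
    )
    def test_counts_for_all_shift_sizes(self, shift_ms, expected):
        """A 5 s trial at 1 kHz with a 2 s window yields the full count table."""
        trial = Trial(np.zeros((5000, 2)), 9.0)
        assert len(sliding_windows(trial, 2.0, shift_ms)) == expected

    def test_offsets_are_shift_multiples_and_ordered(self):
        trial = Trial(np.zeros((5000, 1)), 9.0)
        offs = [s.offset for s in sliding_windows(trial, 2.0, 60)]
        assert offs == sorted(offs)
        assert all(o % 60 == 0 for o in offs)
        assert offs[-1] + 2000 <= 5000

    def test_window_equal_to_trial_gives_zero_segments(self):
        trial = Trial(np.zeros((2000, 1)), 9.0)
        assert sliding_windows(trial, 2.0, 10) == []

    def test_window_longer_than_trial_raises(self):
        with pytest.raises(ValueError, match="longer than"):
            n_windows(1000, 2000, 10)


class TestFFTFeatures:
    def test_peak_bin_at_tone_frequency(self):
        t = np.arange(2000) / 1000.0
        seg = Segment(np.column_stack([np.sin(2 * np.pi * 11 * t), np.zeros(2000)]), 1000.0)
        fm = extract_fft_features(seg)
        assert fm.values.shape == (120, 8) or fm.values.shape == (120, 2)
        assert fm.bin_frequencies[np.argmax(fm.values[:, 0])] == pytest.approx(11.0)

    def test_zero_segment_gives_zero_magnitudes(self):
        fm = extract_fft_features(Segment(np.zeros((2000, 3)), 1000.0))
        assert np.all(fm.values == 0.0)

    def test_default_grid_covers_5_to_35_hz_in_120_bins(self):
        fm = extract_fft_features(Segment(np.zeros((2000, 1)), 1000.0))
        assert fm.n_fs == 120
        assert fm.bin_frequencies[0] == 5.0
        assert fm.bin_frequencies[-1] == pytest.approx(34.75)

    def test_matches_direct_dft_sum(self):
        """FFT magnitudes equal an O(n^2) discrete-Fourier-sum oracle."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64, 3))
        seg = Segment(x, 64.0)
        fm = extract_fft_features(seg, f_lo=5.0, f_hi=21.0, n_bins=64)
        n_fft = 256  # 0.25 Hz resolution at 64 Hz sampling
        padded = np.zeros((n_fft, 3))
        padded[:64] = x
        expected = dft_magnitudes(padded, n_fft, np.arange(20, 84))
        assert np.max(np.abs(fm.values - expected) / (np.abs(expected) + 1e-30)) < 1e-9

    def test_band_beyond_nyquist_raises(self):
        with pytest.raises(ValueError):
            extract_fft_features(Segment(np.zeros((2000, 1)), 1000.0), 5.0, 600.0, 2380)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2000, 2))
        a = extract_fft_features(Segment(x, 1000.0)).values
        b = extract_fft_features(Segment(x.copy(), 1000.0)).values
        assert a.tobytes() == b.tobytes()


class TestNormalization:
    def test_constant_matrix_maps_to_zero(self):
        fm = FeatureMatrix(np.full((4, 2), 7.0), np.arange(4) + 1.0)
        assert np.all(normalize_features(fm).values == 0.0)

    def test_affine_map(self):
        fm = FeatureMatrix(np.array([[2.0], [4.0], [6.0]]), np.arange(3) + 1.0)
        np.testing.assert_allclose(
            normalize_features(fm).values, [[0.0], [0.5], [1.0]]
        )

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.random((20, 4)) * 50 - 10, np.arange(20) + 1.0)
        once = normalize_features(fm)
        twice = normalize_features(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-14)

    def test_non_finite_rejected(self):
        fm = FeatureMatrix(np.array([[np.nan], [1.0]]), np.arange(2) + 1.0)
        with pytest.raises(ValueError):
            normalize_features(fm)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=6, max_size=30))
    def test_output_always_in_unit_interval(self, flat):
        values = np.array(flat)[: 2 * (len(flat) // 2)].reshape(-1, 2)
        fm = FeatureMatrix(values, np.arange(values.shape[0]) + 1.0)
        for scope in ("channel", "matrix"):
            out = normalize_features(fm, scope).values
            assert np.all(out >= 0.0) and np.all(out <= 1.0)
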