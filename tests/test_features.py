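import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eegemo.datasets import TrialSet
from eegemo.features import (FEATURE_ORDER, FeatureMatrix,
                             assemble_feature_matrix, bandpass_rhythm,
                             energy_entropy, hjorth_parameters,
                             load_feature_matrix, psd_band_power,
                             sample_entropy, save_feature_matrix,
                             standard_deviation, wavelet_energy_distribution,
                             wavelet_entropy)

from oracles import sampen_bruteforce

FS = 128.0


def sine(freq, seconds=10.0, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


finite_signals = arrays(np.float64, st.integers(min_value=20, max_value=200),
                        elements=st.floats(-100, 100, allow_nan=False))


class TestBandpass:
    def test_passband_gain_near_unity(self):
        x = sine(10.0)
        y = bandpass_rhythm(x, FS, (8, 13))
        assert abs(np.sqrt((y ** 2).mean()) / np.sqrt((x ** 2).mean()) - 1) < 0.05

    def test_stopband_strongly_attenuated(self):
        y = bandpass_rhythm(sine(10.0), FS, (30, 47))
        assert np.sqrt((y ** 2).mean()) < 0.05

    def test_band_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_rhythm(sine(10.0), FS, (30, 70))


class TestHjorth:
    def test_constant_signal_convention(self):
        assert hjorth_parameters(np.array([5.0, 5.0, 5.0, 5.0])) == (0, 0, 0)

    def test_pure_sine(self):
        act, mob, comp = hjorth_parameters(sine(4.0))
        assert abs(act - 0.5) < 0.005          # A²/2 for unit amplitude
        assert abs(comp - 1.0) < 0.01          # sinusoid: derivative scales only

    def test_white_noise_complexity_above_one(self):
        x = np.random.default_rng(7).standard_normal(10_000)
        _, _, comp = hjorth_parameters(x)
        assert comp > 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hjorth_parameters(np.array([1.0, 2.0]))

    @given(finite_signals)
    @settings(deadline=None, max_examples=50)
    def test_activity_equals_population_variance(self, x):
        act, _, _ = hjorth_parameters(x)
        assert np.isclose(act, standard_deviation(x) ** 2, rtol=1e-10,
                          atol=1e-12)

    @given(finite_signals, st.floats(min_value=0.1, max_value=100))
    @settings(deadline=None, max_examples=50)
    def test_scale_covariance(self, x, c):
        """Mobility/complexity scale-invariant; activity quadratic,
        std linear."""
        if 0 < standard_deviation(x) < 1e-8 * (np.abs(x).max() + 1):
            return  # numerically constant: variance is pure cancellation noise
        a0, m0, c0 = hjorth_parameters(x)
        a1, m1, c1 = hjorth_parameters(c * x)
        assert np.isclose(a1, c * c * a0, rtol=1e-9, atol=1e-12)
        assert np.isclose(m1, m0, rtol=1e-9, atol=1e-12)
        assert np.isclose(c1, c0, rtol=1e-9, atol=1e-12)
        assert np.isclose(standard_deviation(c * x),
                          c * standard_deviation(x), rtol=1e-9, atol=1e-12)


class TestStandardDeviation:
    def test_hand_values(self):
        assert standard_deviation(np.array([1.0, 1.0, 1.0])) == 0.0
        assert standard_deviation(np.array([0.0, 2.0])) == 1.0  # ddof 0
        assert np.isclose(standard_deviation(np.array([0.0, 2.0]), ddof=1),
                          np.sqrt(2))

    def test_unit_variance_noise(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert abs(standard_deviation(x) - 1.0) < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            standard_deviation(np.array([1.0]))


class TestPsdBandPower:
    def test_zero_signal(self):
        assert psd_band_power(np.zeros(512), FS, (8, 13)) == 0.0

    def test_in_band_dominates_out_of_band(self):
        x = sine(10.0, seconds=60.0)
        assert psd_band_power(x, FS, (8, 13)) > 100 * psd_band_power(
            x, FS, (3, 7))

    def test_bin_count_at_fine_resolution(self):
        # 8-s Hann segments -> 0.125 Hz bins; [8, 13] holds >= 40 of them
        freqs_in_band = np.arange(0, FS / 2 + 0.125, 0.125)
        n_bins = ((freqs_in_band >= 8) & (freqs_in_band <= 13)).sum()
        assert n_bins >= 40
        x = sine(10.0, seconds=60.0)
        assert psd_band_power(x, FS, (8, 13), window_s=8.0) > 0

    def test_no_bin_in_band_rejected(self):
        with pytest.raises(ValueError):
            psd_band_power(sine(10.0), FS, (8.1, 8.3))  # 0.5 Hz bins

    def test_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            psd_band_power(np.zeros(100), FS, (8, 13))


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(50, 3.3)) == 0.0

    def test_periodic_example_matches_bruteforce(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        assert sample_entropy(x, m=2, r=0.5) == sampen_bruteforce(x, m=2,
                                                                  r=0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_signals(self, seed):
        """Tree-based pair counting agrees exactly with O(n²) enumeration."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(5, 61))
            kind = rng.integers(3)
            if kind == 0:
                x = rng.standard_normal(n)
            elif kind == 1:
                x = np.sin(0.3 * np.arange(n)) + 0.1 * rng.standard_normal(n)
            else:
                x = np.round(rng.uniform(0, 3, n))  # ties at the tolerance
            assert sample_entropy(x) == sampen_bruteforce(x)

    def test_noise_more_irregular_than_sine(self):
        rng = np.random.default_rng(10)
        noise = rng.uniform(size=500)
        tone = sine(4.0, seconds=500 / FS)
        assert sample_entropy(noise) > sample_entropy(tone)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2)


class TestWaveletEntropy:
    def test_single_component_distribution_has_zero_entropy(self):
        assert energy_entropy(np.array([1.0, 0, 0, 0, 0])) == 0.0

    def test_uniform_distribution_attains_log_n(self):
        assert np.isclose(energy_entropy(np.full(5, 0.2)), np.log(5))

    def test_tone_plus_noise_strictly_inside_bounds(self):
        rng = np.random.default_rng(4)
        x = sine(10.0) + 0.05 * rng.standard_normal(1280)
        dist = wavelet_energy_distribution(x)
        assert np.isclose(dist.p.sum(), 1.0)
        we = wavelet_entropy(x)
        assert 0 < we < np.log(5)

    def test_all_zero_signal(self):
        with pytest.raises(ValueError):
            wavelet_entropy(np.zeros(256))
        assert wavelet_entropy(np.zeros(256), on_zero="zero") == 0.0

    @given(finite_signals)
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_normalization(self, x):
        if np.ptp(x) == 0 or np.abs(x).max() < 1e-80:  # energy underflows
            return
        dist = wavelet_energy_distribution(x)
        assert np.isclose(dist.p.sum(), 1.0)
        assert -1e-12 <= energy_entropy(dist) <= np.log(5) + 1e-12

    @given(finite_signals, st.floats(min_value=0.1, max_value=100))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, x, c):
        if np.ptp(x) == 0 or np.abs(x).max() < 1e-80:  # energy underflows
            return
        assert np.isclose(wavelet_entropy(c * x), wavelet_entropy(x),
                          rtol=1e-9, atol=1e-9)


class TestAssembleFeatureMatrix:
    def _trialset(self, n_trials=3, n_channels=2, seconds=3.0):
        rng = np.random.default_rng(8)
        n = int(seconds * FS)
        return TrialSet(signals=rng.standard_normal((n_trials, n_channels, n)),
                        fs=FS, subject_id=np.arange(n_trials),
                        session_id=np.zeros(n_trials, int),
                        ratings=np.full(n_trials, 7.0),
                        channel_names=["Fp1", "Fp2"][:n_channels])

    def test_single_trial_two_channels(self):
        ts = self._trialset(n_trials=1)
        fm = assemble_feature_matrix(ts, np.array([1]))
        assert fm.values.shape == (1, 20)
        assert len(set(fm.column_names)) == 20
        assert fm.column_names[:2] == ["Fp1__activity", "Fp1__mobility"]
        assert fm.column_names[10] == "Fp2__activity"

    def test_column_count_and_order(self):
        ts = self._trialset()
        fm = assemble_feature_matrix(ts, np.array([1, 0, 1]))
        assert fm.n_features == ts.n_channels * len(FEATURE_ORDER)
        # channel-major, Table-order within channel
        for c, ch in enumerate(ts.channel_names):
            for k, feat in enumerate(FEATURE_ORDER):
                assert fm.column_names[c * 10 + k] == f"{ch}__{feat}"

    def test_rows_follow_trial_order(self):
        ts = self._trialset(n_trials=4)
        fm = assemble_feature_matrix(ts, np.array([1, 0, 1, 0]))
        for t in range(4):
            act, _, _ = hjorth_parameters(ts.signals[t, 0])
            assert np.isclose(fm.values[t, 0], act)

    def test_extractor_subset(self):
        ts = self._trialset()
        fm = assemble_feature_matrix(ts, np.array([1, 0, 1]),
                                     extractors=["activity", "sampen"])
        assert fm.n_features == 4
        assert fm.column_names == ["Fp1__activity", "Fp1__sampen",
                                   "Fp2__activity", "Fp2__sampen"]

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature_matrix(self._trialset(), np.array([1, 0]))

    def test_nonfinite_feature_flagged_with_context(self):
        with pytest.raises(ValueError, match="column"):
            FeatureMatrix(values=np.array([[1.0, np.inf]]),
                          column_names=["a", "b"], labels=[1],
                          subject_id=[0])

    def test_csv_roundtrip(self, tmp_path):
        ts = self._trialset()
        fm = assemble_feature_matrix(ts, np.array([1, 0, 1]))
        save_feature_matrix(fm, tmp_path / "fm.csv")
        back = load_feature_matrix(tmp_path / "fm.csv")
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-15)
        assert back.column_names == fm.column_names
        np.testing.assert_array_equal(back.labels, fm.labels)
        np.testing.assert_array_equal(back.subject_id, fm.subject_id)
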