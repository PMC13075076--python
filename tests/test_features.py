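"""Spectral oracles, ERD identities and feature-matrix contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tonguemi as tm
from tonguemi.features import FeatureMatrix, FeatureVector


def direct_periodogram(x, fs, nfft=256):
    """Independent single-window modified-periodogram oracle:
    Hamming window, mean removal, one-sided density scaling."""
    x = np.asarray(x, dtype=float)
    w = np.hamming(len(x))
    xw = (x - x.mean()) * w
    spec = np.fft.rfft(xw, n=nfft)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w ** 2))
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    return np.fft.rfftfreq(nfft, 1 / fs), psd


class TestWelch:
    def test_nine_windows_per_5s_segment(self):
        seg = np.random.default_rng(0).standard_normal((14, 1280))
        est = tm.welch_psd(seg, 256.0)
        assert est.n_windows == 9
        assert est.nfft == 256
        assert est.freqs[0] == 0.0 and est.freqs[-1] == 128.0
        assert np.all(est.psd >= 0)
        assert est.freqs[1] - est.freqs[0] == pytest.approx(1.0)

    def test_degenerate_single_window_equals_periodogram(self):
        # a 1 s input makes Welch collapse to one modified periodogram
        rng = np.random.default_rng(1)
        x = rng.standard_normal(256)
        est = tm.welch_psd(x[None, :], 256.0)
        assert est.n_windows == 1
        freqs, oracle = direct_periodogram(x, 256.0)
        np.testing.assert_allclose(est.freqs, freqs)
        np.testing.assert_allclose(est.psd[0], oracle, rtol=1e-10)

    def test_sinusoid_peak_at_its_frequency(self):
        t = np.arange(1280) / 256.0
        x = np.sin(2 * np.pi * 11.0 * t)
        est = tm.welch_psd(x[None, :], 256.0)
        assert est.freqs[int(np.argmax(est.psd[0]))] == pytest.approx(11.0)

    def test_white_noise_total_power_parseval(self):
        rng = np.random.default_rng(2)
        sigma = 3.0
        x = rng.normal(0, sigma, (4, 1280))
        est = tm.welch_psd(x, 256.0)
        total = np.trapezoid(est.psd, est.freqs, axis=-1)
        assert float(total.mean()) == pytest.approx(sigma ** 2, rel=0.10)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            tm.welch_psd(np.zeros((2, 100)), 256.0)


class TestBandPower:
    def _flat_estimate(self, value=2.5):
        freqs = np.arange(0, 129.0)
        psd = np.full((3, freqs.size), value)
        return tm.SpectralEstimate(freqs=freqs, psd=psd, n_windows=9,
                                   window_length_s=1.0,
                                   overlap_fraction=0.5, nfft=256)

    def test_flat_psd_gives_its_level(self):
        np.testing.assert_allclose(
            tm.band_power(self._flat_estimate(2.5), tm.ALPHA), 2.5)

    def test_alpha_uses_exactly_three_inclusive_bins(self):
        est = self._flat_estimate(0.0)
        est.psd[:, [10, 11, 12]] = 3.0
        np.testing.assert_allclose(tm.band_power(est, tm.ALPHA), 3.0)
        est.psd[:, [9, 13]] = 99.0  # outside the inclusive edges
        np.testing.assert_allclose(tm.band_power(est, tm.ALPHA), 3.0)

    def test_linearity(self):
        est = self._flat_estimate(1.3)
        doubled = tm.SpectralEstimate(
            freqs=est.freqs, psd=2 * est.psd, n_windows=9,
            window_length_s=1.0, overlap_fraction=0.5, nfft=256)
        np.testing.assert_allclose(
            tm.band_power(doubled, tm.BETA),
            2 * tm.band_power(est, tm.BETA))

    def test_band_outside_grid_rejected(self):
        est = self._flat_estimate()
        with pytest.raises(ValueError):
            tm.band_power(est, tm.BandSpec("x", 500.0, 600.0))


class TestErdPercent:
    @pytest.mark.parametrize("p_b,p_i,expected", [
        (10.0, 7.0, 30.0),
        (5.0, 5.0, 0.0),
        (4.0, 6.0, -50.0),
    ])
    def test_identities(self, p_b, p_i, expected):
        assert tm.erd_percent(p_b, p_i) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            tm.erd_percent(0.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p_b=st.floats(1e-6, 1e6), p_i=st.floats(0.0, 1e6))
    def test_bounded_above_by_100(self, p_b, p_i):
        val = tm.erd_percent(p_b, p_i)
        assert val <= 100.0
        if p_i == 0.0:
            assert val == 100.0


class TestTrialFeatures:
    def test_feature_vector_length_and_order(self, tiny_study):
        ep = tm.preprocess_study(tiny_study[:1])[0]
        fv = tm.trial_features(ep)
        assert fv.erd.shape == (14,)
        assert fv.command == tiny_study[0].command

    def test_zero_baseline_channel_named(self, montage):
        ep = tm.TrialEpoch(
            baseline=np.zeros((14, 1280)), imagery=np.ones((14, 1280)),
            execution=None, command="LL", fs=256.0, channels=montage)
        with pytest.raises(ValueError, match="AF3"):
            tm.trial_features(ep)

    def test_null_effect_grand_average_erd_near_zero(self):
        cfg = tm.SimulationConfig(
            n_subjects=4, trials_per_command_per_session=6,
            nominal_erd_percent={c: 0.0 for c in tm.COMMANDS}, seed=5)
        epochs = tm.preprocess_study(tm.simulate_study(cfg, seed=5))
        erd_map = tm.grand_average_erd(epochs)  # 288 trials pooled
        assert abs(erd_map.mean()) < 3.0
        assert np.abs(erd_map).max() < 12.0


class TestFeatureMatrix:
    def test_study_matrix_shape(self, tiny_study_features, tiny_study):
        assert tiny_study_features.X.shape == (len(tiny_study), 14)

    def test_concatenation_is_row_wise(self, tiny_study):
        e1 = tm.preprocess_study(tiny_study[:2])
        e2 = tm.preprocess_study(tiny_study[2:4])
        both = tm.build_feature_matrix(e1 + e2)
        parts = FeatureMatrix.concat(
            [tm.build_feature_matrix(e1), tm.build_feature_matrix(e2)])
        np.testing.assert_allclose(both.X, parts.X)

    def test_beta_band_same_shape_different_values(self, tiny_study):
        epochs = tm.preprocess_study(tiny_study[:4])
        a = tm.build_feature_matrix(epochs, tm.ALPHA)
        b = tm.build_feature_matrix(epochs, tm.BETA)
        assert a.X.shape == b.X.shape
        assert not np.allclose(a.X, b.X)

    def test_out_of_range_erd_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(erd=np.full(14, 101.0), command="LL")


class TestTopography:
    def test_single_trial_map_equals_vector(self, tiny_study_features):
        fm = tiny_study_features
        first_ll = fm.filter_commands(["LL"])
        one = FeatureMatrix(first_ll.frame.iloc[:1], fm.channels)
        series = tm.grand_average_topography(one, "LL")
        np.testing.assert_allclose(series.to_numpy(), one.X[0])

    def test_missing_command_rejected(self, tiny_study_features):
        only_ll = tiny_study_features.filter_commands(["LL"])
        with pytest.raises(ValueError):
            tm.grand_average_topography(only_ll, "CR")

    def test_band_power_map_positive(self, tiny_study):
        epochs = tm.preprocess_study(tiny_study[:4])
        series = tm.band_power_topography(epochs, tm.ALPHA, "baseline")
        assert (series > 0).all()
        assert list(series.index) == list(epochs[0].channels.labels)
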