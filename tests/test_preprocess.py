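"""Filtering, resampling, embedding, and PCA.

Filter assertions are checked against the designed transfer function
(``sosfreqz`` of the same filter), applied twice for the forward-backward
pass, so the oracle is independent of the time-domain filtering path.
"""

import numpy as np
import pytest
from scipy import signal

from iedmap.containers import Recording
from iedmap.exceptions import ParameterError
from iedmap.preprocess import bandpass, embed, notch, pca_reduce, resample


def _rec(data, fs=1200.0):
    return Recording(data=np.atleast_2d(data), fs=fs)


def _sine(freq, fs=1200.0, duration=10.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _designed_gain(freq, fs, low, high, order=4):
    """|H(f)|^2 of the Butterworth band-pass: zero-phase = squared magnitude."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass(_rec(_sine(40.0)), 20.0, 70.0)
        mid = out.data[0, 2400:-2400]
        expected = _designed_gain(40.0, 1200.0, 20.0, 70.0)
        assert np.max(np.abs(mid)) == pytest.approx(expected, rel=0.02)
        assert abs(expected - 1.0) < 0.02  # 40 Hz is well inside the band

    def test_stopband_tone_attenuated_20db(self):
        out = bandpass(_rec(_sine(5.0)), 20.0, 70.0)
        mid = out.data[0, 2400:-2400]
        assert np.max(np.abs(mid)) < 10 ** (-20 / 20)
        assert _designed_gain(5.0, 1200.0, 20.0, 70.0) < 10 ** (-20 / 20)

    def test_zero_input_zero_output(self):
        out = bandpass(_rec(np.zeros(4000)), 20.0, 70.0)
        assert np.all(out.data == 0)

    def test_history_appended_and_length_kept(self):
        rec = _rec(_sine(30.0))
        out = bandpass(rec, 20.0, 70.0)
        assert out.n_samples == rec.n_samples
        assert out.history[-1]["step"] == "bandpass"

    @pytest.mark.parametrize("low,high", [(0.0, 70.0), (70.0, 20.0), (20.0, 700.0)])
    def test_invalid_band_rejected(self, low, high):
        with pytest.raises(ParameterError):
            bandpass(_rec(_sine(30.0)), low, high)


class TestNotch:
    def test_mains_tone_suppressed(self):
        out = notch(_rec(_sine(60.0)), 60.0)
        mid = out.data[0, 2400:-2400]
        assert np.sqrt(np.mean(mid**2)) < 0.05 * np.sqrt(0.5)

    def test_neighbouring_tone_preserved(self):
        out = notch(_rec(_sine(40.0)), 60.0)
        mid = out.data[0, 2400:-2400]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ParameterError):
            notch(_rec(_sine(40.0)), 600.0)


class TestResample:
    def test_sample_count(self):
        rec = _rec(np.random.default_rng(0).standard_normal((3, 144000)))
        rec = bandpass(rec, 20.0, 70.0)
        out = resample(rec, 150.0)
        assert out.n_samples == 18000
        assert out.fs == 150.0

    def test_tone_amplitude_preserved(self):
        rec = bandpass(_rec(_sine(40.0, duration=20.0)), 20.0, 70.0)
        out = resample(rec, 150.0)
        mid = out.data[0, 300:-300]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_identity_rate(self):
        rec = _rec(_sine(40.0))
        out = resample(rec, rec.fs)
        np.testing.assert_allclose(out.data, rec.data)

    def test_warns_without_antialias_band(self):
        with pytest.warns(UserWarning):
            resample(_rec(_sine(40.0)), 150.0)

    def test_bad_rate_rejected(self):
        with pytest.raises(ParameterError):
            resample(_rec(_sine(40.0)), -1.0)


class TestEmbed:
    def test_lag_count_73ms_at_150hz(self):
        rec = _rec(np.random.default_rng(1).standard_normal((2, 1500)), fs=150.0)
        emb = embed(rec, 73.0)
        assert emb.n_lags == 11
        np.testing.assert_array_equal(emb.lags, np.arange(-5, 6))

    def test_shape_contract(self):
        rec = _rec(np.random.default_rng(2).standard_normal((3, 200)), fs=150.0)
        emb = embed(rec, 73.0)
        assert emb.matrix.shape == (200 - 10, 3 * 11)

    def test_lag_zero_columns_recover_input(self):
        rec = _rec(np.random.default_rng(3).standard_normal((3, 300)), fs=150.0)
        emb = embed(rec, 73.0)
        half = emb.valid_offset
        for c in range(3):
            col = emb.matrix[:, c * emb.n_lags + half]
            np.testing.assert_array_equal(col, rec.data[c, half:-half])

    def test_constant_channel_gives_constant_columns(self):
        data = np.vstack([np.full(120, 3.5), np.random.default_rng(4).standard_normal(120)])
        emb = embed(_rec(data, fs=150.0), 73.0)
        assert np.ptp(emb.matrix[:, : emb.n_lags]) == 0

    def test_window_below_3_samples_rejected(self):
        rec = _rec(np.zeros((1, 100)), fs=150.0)
        with pytest.raises(ParameterError):
            embed(rec, 10.0)  # 1.5 samples at 150 Hz


class TestPCA:
    def test_full_basis_captures_all_variance(self, rng):
        rec = _rec(rng.standard_normal((2, 400)), fs=150.0)
        emb = embed(rec, 73.0)
        red = pca_reduce(emb, emb.matrix.shape[1])
        assert red.explained_variance_fraction == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_structure(self, rng):
        u = rng.standard_normal(500)
        v = rng.standard_normal(22)
        emb_like = _rec((np.outer(v, u) + 1e-6 * rng.standard_normal((22, 500)))[:2], fs=150.0)
        # build a genuine rank-1 embedded matrix directly
        from iedmap.preprocess import EmbeddedData

        X = np.outer(u, v) + 1e-6 * rng.standard_normal((500, 22))
        emb = EmbeddedData(matrix=X, lags=np.arange(-5, 6), fs=150.0, valid_offset=5, n_channels=2)
        red = pca_reduce(emb, 1, standardize=False)
        assert red.explained_variance_fraction > 0.99

    def test_scores_uncorrelated(self, rng):
        rec = _rec(rng.standard_normal((4, 1000)), fs=150.0)
        red = pca_reduce(embed(rec, 73.0), 10)
        C = np.cov(red.scores, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(C))

    def test_out_of_range_components_rejected(self, rng):
        emb = embed(_rec(rng.standard_normal((2, 100)), fs=150.0), 73.0)
        with pytest.raises(ParameterError):
            pca_reduce(emb, 1000)
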