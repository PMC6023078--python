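"""Wiener denoiser: STFT round trip, noise PSD, decision-directed SNR
tracking, gain law, and end-to-end SNR improvement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpi.core import InsufficientNoiseError, RawRecording
from bpi.denoise import (
    WienerDenoiser,
    WienerParams,
    decision_directed_snr,
    denoise_recording,
    estimate_noise_psd,
    istft,
    stft,
    wiener_gain,
)
from bpi.synth import measure_snr_db, render_acoustic_parts, render_envelope

FS = 22050.0


def _rec(x, lead=1.0):
    return RawRecording(np.asarray(x, float), FS, lead)


class TestStft:
    def test_zero_signal_zero_frames(self):
        sf = stft(_rec(np.zeros(44100)))
        assert np.all(sf.frames == 0)
        assert sf.frames.shape[0] == sf.frame_len // 2 + 1

    def test_sinusoid_energy_concentrates(self):
        params = WienerParams()
        L = params.frame_len(FS)
        k = 40  # bin-centre frequency
        f0 = k * FS / L
        t = np.arange(int(2 * FS)) / FS
        sf = stft(_rec(0.5 * np.sin(2 * np.pi * f0 * t)), params)
        power = np.abs(sf.frames) ** 2
        mid = power[:, sf.n_frames // 2]
        # Hann analysis window: the main lobe spans the centre bin +/- 1
        assert mid[k - 1 : k + 2].sum() / mid.sum() >= 0.95
        assert np.argmax(mid) == k

    def test_round_trip_identity(self, rng):
        x = np.clip(rng.standard_normal(44100) * 0.2, -1, 1)
        sf = stft(_rec(x))
        y = istft(sf)
        assert y.size == x.size
        assert np.max(np.abs(y - x)) < 1e-6 * np.max(np.abs(x))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            stft(_rec(np.zeros(100), lead=0.001))


class TestNoisePsd:
    def test_white_noise_level(self):
        """Flat PSD estimate within 20% of the analytic white-noise level,
        averaged over bins and 10 seeded trials."""
        params = WienerParams()
        L = params.frame_len(FS)
        sigma2 = 0.01
        # rfft of windowed noise: E|X_k|^2 = sigma^2 * sum(w^2) away from DC/Nyquist
        from scipy.signal import windows

        expected = sigma2 * np.sum(windows.hann(L, sym=False) ** 2)
        ratios = []
        for trial in range(10):
            x = np.random.default_rng(trial).normal(0, np.sqrt(sigma2), int(2 * FS))
            sf = stft(_rec(np.clip(x, -1, 1)), params)
            psd = estimate_noise_psd(sf, 1.0)
            ratios.append(np.mean(psd[1:-1]) / expected)
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_zero_lead_gives_floored_psd(self):
        x = np.zeros(44100)
        x[30000:] = 0.1
        psd = estimate_noise_psd(stft(_rec(x)), 1.0)
        assert np.all(psd > 0)

    def test_only_lead_frames_used(self):
        """A loud burst just after the 1 s lead must not leak into the
        noise estimate."""
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0, 0.01, 44100), -1, 1)
        x[22050:23000] = 0.9
        sf = stft(_rec(x))
        psd_with_burst = estimate_noise_psd(sf, 1.0)
        x2 = x.copy()
        x2[22050:23000] = np.clip(rng.normal(0, 0.01, 950), -1, 1)
        psd_quiet = estimate_noise_psd(stft(_rec(x2)), 1.0)
        assert np.allclose(psd_with_burst, psd_quiet)

    def test_short_lead_rejected(self):
        with pytest.raises(InsufficientNoiseError):
            estimate_noise_psd(stft(_rec(np.zeros(44100))), 0.01)


class TestDecisionDirected:
    def test_alpha_zero_is_ml_estimate(self, rng):
        x = np.clip(rng.standard_normal(44100) * 0.1, -1, 1)
        sf = stft(_rec(x))
        psd = estimate_noise_psd(sf, 1.0)
        track = decision_directed_snr(sf, psd, alpha=0.0)
        expected = np.maximum(track.snr_posteriori - 1.0, 0.0)
        assert np.allclose(track.snr_priori, expected)

    def test_noise_only_snr_near_zero(self):
        """Mean a-priori SNR over bins stays < 0.5 on pure noise."""
        means = []
        for trial in range(10):
            x = np.clip(np.random.default_rng(trial).normal(0, 0.05, 44100), -1, 1)
            sf = stft(_rec(x))
            track = decision_directed_snr(sf, estimate_noise_psd(sf, 1.0), 0.98)
            means.append(track.snr_priori.mean())
        assert np.mean(means) < 0.5

    def test_tone_snr_converges(self):
        """Stationary high-SNR tone: tracked a-priori SNR within 3 dB of the
        true bin SNR after 10 frames."""
        params = WienerParams()
        L, hop = params.frame_len(FS), params.hop(FS)
        k = 50
        f0 = k * FS / L
        rng = np.random.default_rng(7)
        sigma = 0.003
        t = np.arange(44100) / FS
        amp = 0.3
        x = np.clip(amp * np.sin(2 * np.pi * f0 * t) + rng.normal(0, sigma, t.size), -1, 1)
        x[:22050] = np.clip(rng.normal(0, sigma, 22050), -1, 1)  # noise-only lead
        sf = stft(_rec(x))
        track = decision_directed_snr(sf, estimate_noise_psd(sf, 1.0), 0.98)
        # true bin SNR: tone power in bin k over noise power per bin
        from scipy.signal import windows

        win = windows.hann(L, sym=False)
        tone_bin = (amp * np.abs(np.fft.rfft(np.sin(2 * np.pi * f0 * np.arange(L) / FS) * win))[k]) ** 2
        noise_bin = sigma**2 * np.sum(win**2)
        true_snr_db = 10 * np.log10(tone_bin / noise_bin)
        tone_frames = range(sf.n_frames * 2 // 3, sf.n_frames * 2 // 3 + 10)
        tracked = 10 * np.log10(np.mean([track.snr_priori[k, f] for f in tone_frames]))
        assert abs(tracked - true_snr_db) < 3.0

    def test_bad_alpha_rejected(self, rng):
        sf = stft(_rec(np.clip(rng.standard_normal(44100) * 0.1, -1, 1)))
        psd = estimate_noise_psd(sf, 1.0)
        for alpha in (-0.1, 1.0):
            with pytest.raises(ValueError):
                decision_directed_snr(sf, psd, alpha)


class TestWienerGain:
    @pytest.mark.parametrize(
        "snr,expected", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)]
    )
    def test_gain_law(self, snr, expected):
        assert wiener_gain(snr) == pytest.approx(expected)

    def test_floor(self):
        assert wiener_gain(0.0, gain_floor=0.05) == 0.05

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            wiener_gain(-1.0)

    @given(st.floats(min_value=0, max_value=1e12), st.floats(min_value=0, max_value=1e12))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, s1, s2):
        g1, g2 = wiener_gain(s1), wiener_gain(s2)
        assert 0 <= g1 < 1 and 0 <= g2 < 1
        if s1 <= s2:
            assert g1 <= g2

    def test_infinite_snr_limit(self):
        assert wiener_gain(np.inf) == 1.0


class TestDenoiseRecording:
    def test_zero_in_zero_out(self):
        out = denoise_recording(_rec(np.zeros(44100)))
        assert np.all(out.samples == 0)
        assert out.n_samples == 44100

    def test_clean_input_preserved(self, specs4):
        """Essentially noise-free breath recording passes through with
        correlation >= 0.99."""
        env = render_envelope(specs4[0])
        breath, noise = render_acoustic_parts(env, 60.0, rng=np.random.default_rng(2))
        rec = _rec(breath + noise)
        out = denoise_recording(rec)
        corr = np.corrcoef(rec.samples, out.samples)[0, 1]
        assert corr >= 0.99
        assert out.n_samples == rec.n_samples
        assert np.max(np.abs(out.samples)) <= np.max(np.abs(rec.samples)) * 1.01

    @pytest.mark.parametrize("snr_in", [0.0, 5.0, 10.0])
    def test_snr_improvement(self, specs4, snr_in):
        """Mean output SNR strictly exceeds input SNR at 0/5/10 dB over 10
        seeded trials (breath + stationary white noise)."""
        env = render_envelope(specs4[0])
        deltas = []
        for trial in range(10):
            b, n = render_acoustic_parts(env, snr_in, rng=np.random.default_rng(trial))
            out = denoise_recording(_rec(b + n))
            deltas.append(measure_snr_db(b, out.samples) - measure_snr_db(b, b + n))
        assert np.mean(deltas) > 0


class TestWienerDenoiserEstimator:
    def test_sklearn_transform_matches_function(self, specs4):
        env = render_envelope(specs4[0])
        b, n = render_acoustic_parts(env, 10.0, rng=np.random.default_rng(4))
        x = b + n
        est = WienerDenoiser().fit(x[None, :])
        row = est.transform(x[None, :])[0]
        ref = denoise_recording(_rec(x)).samples
        assert np.array_equal(row, ref)

    def test_get_set_params_round_trip(self):
        est = WienerDenoiser(alpha=0.9)
        est2 = WienerDenoiser().set_params(**est.get_params())
        assert est2.get_params() == est.get_params()
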