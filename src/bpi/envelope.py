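"""Breath-envelope extraction: 22,050 Hz audio -> 100 Hz envelope.

The chain mirrors the processing stack of the acquisition platform: the
denoised recording is anti-alias resampled to 1000 Hz for dimension
reduction, full-wave rectified (amplitude demodulation), low-pass filtered
with a zero-phase 4th-order Butterworth at 2 Hz (the 0.2-0.8 Hz breathing
band plus modulation harmonics), clipped of residual negative ringing, and
decimated to 100 Hz.  A 10 s window therefore becomes a 1000-sample
non-negative envelope.  Normalisation removes the offset (minimum) and
scales the peak to 1, so classification compares shapes, not loudness.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import BreathEnvelope, RawRecording

__all__ = ["downsample", "extract_envelope", "normalize_envelope", "EnvelopeExtractor"]

DEFAULT_INTERMEDIATE_RATE_HZ = 1000.0
DEFAULT_ENV_RATE_HZ = 100.0
DEFAULT_CUTOFF_HZ = 2.0
_BUTTER_ORDER = 4


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")


def downsample(rec: RawRecording, target_rate_hz: float) -> RawRecording:
    """Anti-alias filtered resampling to a lower rate.

    Polyphase FIR resampling; content above the target Nyquist is attenuated
    by well over 40 dB.  Upsampling requests are rejected.
    """
    if target_rate_hz >= rec.sample_rate_hz:
        raise ValueError(
            f"target rate {target_rate_hz} Hz must be below input rate {rec.sample_rate_hz} Hz"
        )
    y = _resample(rec.samples, rec.sample_rate_hz, target_rate_hz)
    n_expected = int(round(rec.duration_s * target_rate_hz))
    y = y[:n_expected]
    # polyphase edge ringing can poke a hair above full scale
    return RawRecording(np.clip(y, -1.0, 1.0), target_rate_hz, rec.silence_lead_s)


def extract_envelope(
    rec_1k: RawRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    env_rate_hz: float = DEFAULT_ENV_RATE_HZ,
) -> BreathEnvelope:
    """Demodulate a low-rate recording into a non-negative breath envelope.

    Full-wave rectification, zero-phase Butterworth low-pass at
    ``cutoff_hz``, clipping of residual filter ringing below zero, then
    plain decimation to ``env_rate_hz`` (the low-pass already guarantees
    anti-aliasing for the envelope Nyquist).
    """
    if cutoff_hz >= env_rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below envelope Nyquist {env_rate_hz / 2} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    step = rec_1k.sample_rate_hz / env_rate_hz
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError(
            f"envelope rate {env_rate_hz} Hz must divide recording rate {rec_1k.sample_rate_hz} Hz"
        )
    rect = np.abs(rec_1k.samples)
    sos = signal.butter(_BUTTER_ORDER, cutoff_hz, fs=rec_1k.sample_rate_hz, output="sos")
    smooth = signal.sosfiltfilt(sos, rect)
    smooth = np.clip(smooth, 0.0, None)
    env = smooth[:: int(round(step))]
    return BreathEnvelope(env, rate_hz=env_rate_hz)


def normalize_envelope(env: BreathEnvelope) -> BreathEnvelope:
    """Offset removal (subtract minimum) and peak scaling to 1.

    Scale-invariant; a constant envelope normalises to all zeros, and an
    all-zero envelope is returned unchanged.
    """
    if not np.all(np.isfinite(env.values)):
        raise ValueError("non-finite envelope values")
    y = env.values - env.values.min()
    peak = y.max()
    if peak > 0:
        y = y / peak
    return BreathEnvelope(y, env.rate_hz, env.class_label)


class EnvelopeExtractor(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: raw audio rows -> normalised envelope rows.

    ``X`` is ``(n_recordings, n_audio_samples)`` at ``sample_rate_hz``;
    output is ``(n_recordings, duration_s * env_rate_hz)``.  Set
    ``normalize=False`` to keep raw (non-negative, unscaled) envelopes.
    """

    def __init__(
        self,
        sample_rate_hz: float = 22050.0,
        intermediate_rate_hz: float = DEFAULT_INTERMEDIATE_RATE_HZ,
        env_rate_hz: float = DEFAULT_ENV_RATE_HZ,
        cutoff_hz: float = DEFAULT_CUTOFF_HZ,
        normalize: bool = True,
    ):
        self.sample_rate_hz = sample_rate_hz
        self.intermediate_rate_hz = intermediate_rate_hz
        self.env_rate_hz = env_rate_hz
        self.cutoff_hz = cutoff_hz
        self.normalize = normalize

    def fit(self, X, y=None):
        if not self.env_rate_hz < self.intermediate_rate_hz < self.sample_rate_hz:
            raise ValueError("rates must satisfy env < intermediate < sample rate")
        X = check_array(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        return self

    def _one(self, row: np.ndarray) -> np.ndarray:
        rec = RawRecording(np.clip(row, -1.0, 1.0), self.sample_rate_hz, 0.0)
        rec_lo = downsample(rec, self.intermediate_rate_hz)
        env = extract_envelope(rec_lo, self.cutoff_hz, self.env_rate_hz)
        if self.normalize:
            env = normalize_envelope(env)
        return env.values

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=np.float64)
        return np.stack([self._one(row) for row in X])
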