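"""Core containers shared across the breathing-pattern-interpretation pipeline.

A breathing pattern (BP) travels through the system in two representations:

* :class:`RawRecording` — a fixed-length mono audio window as captured by a
  close-talking microphone (22,050 Hz, 10 s, with a guaranteed signal-free
  leading second used for noise estimation).
* :class:`BreathEnvelope` — the slow, non-negative amplitude contour of the
  breath sound after denoising, rectification and low-pass filtering,
  sub-sampled to 100 Hz.  This is the unit that gets classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RawRecording",
    "BreathEnvelope",
    "FormatError",
    "InvalidSpecError",
    "InvalidWarpError",
    "InsufficientNoiseError",
    "VocabularyMismatchError",
    "EmptyLibraryError",
]


class FormatError(ValueError):
    """A persisted artifact (manifest, CSV, WAV) is malformed or missing."""


class InvalidSpecError(ValueError):
    """A synthetic breath-class specification violates its invariants."""


class InvalidWarpError(ValueError):
    """A time warp would push breath events outside the recording window."""


class InsufficientNoiseError(ValueError):
    """The leading silence is too short to estimate the noise spectrum."""


class VocabularyMismatchError(ValueError):
    """Template classes and the phrase vocabulary do not agree."""


class EmptyLibraryError(ValueError):
    """Classification was requested against a library with no templates."""


# amplitude slack for float round-off when validating peak-normalised audio
_PEAK_TOL = 1e-9


@dataclass
class RawRecording:
    """Fixed-length mono audio window.

    Parameters
    ----------
    samples
        Amplitude samples, dimensionless, in ``[-1, 1]``.
    sample_rate_hz
        Sampling rate; the acquisition protocol records at 22,050 Hz.
    silence_lead_s
        Duration of the guaranteed signal-free lead (background noise only)
        at the start of the window; used downstream for noise estimation.
    """

    samples: np.ndarray
    sample_rate_hz: float = 22050.0
    silence_lead_s: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D mono, got ndim={self.samples.ndim}")
        if self.samples.size == 0:
            raise ValueError("empty recording")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in recording")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + _PEAK_TOL:
            raise ValueError(f"samples exceed full scale: peak={peak:.6g}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0 <= self.silence_lead_s < self.duration_s:
            raise ValueError(
                f"silence_lead_s={self.silence_lead_s} must lie in [0, duration={self.duration_s})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class BreathEnvelope:
    """Non-negative low-rate envelope of one breathing pattern.

    ``values`` are non-negative before normalisation; after
    :func:`bpi.envelope.normalize_envelope` they lie in ``[0, 1]`` with the
    peak at exactly 1 (unless the envelope is identically zero).
    """

    values: np.ndarray
    rate_hz: float = 100.0
    class_label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if self.values.size == 0:
            raise ValueError("empty envelope")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite envelope values")
        if np.any(self.values < -_PEAK_TOL):
            raise ValueError("envelope values must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz
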