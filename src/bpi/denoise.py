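"""Single-channel Wiener denoising with decision-directed SNR tracking.

The recording's guaranteed 1 s signal-free lead supplies the noise power
spectrum (noise assumed stationary over the 10 s window).  Per short-time
frame and frequency bin, the a-posteriori SNR ``|X(f,t)|^2 / P_noise(f)``
drives the decision-directed recursion for the a-priori SNR

    xi(f,t) = alpha * G(f,t-1)^2 * gamma(f,t-1) + (1-alpha) * max(gamma(f,t)-1, 0)

and the Wiener gain ``W(f) = xi / (xi + 1)`` (floored to limit musical
noise) attenuates each bin before overlap-add resynthesis.

Frames are left-aligned (frame ``t`` covers samples ``[t*hop, t*hop+L)``)
so "frames wholly inside the leading silence" is plain index arithmetic;
the periodic Hann window at 50% hop overlap-adds to exactly 1, giving an
analysis–synthesis round trip exact to float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.signal import windows
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import InsufficientNoiseError, RawRecording

__all__ = [
    "WienerParams",
    "SpectralFrames",
    "SnrTrack",
    "stft",
    "istft",
    "estimate_noise_psd",
    "decision_directed_snr",
    "wiener_gain",
    "denoise_recording",
    "WienerDenoiser",
]


@dataclass
class WienerParams:
    """Tunables of the Wiener enhancement stage.

    alpha : decision-directed smoothing constant in [0, 1).
    noise_from_lead_s : length of the leading silence used for the noise PSD.
    gain_floor : lower bound on the spectral gain (suppresses musical noise).
    frame_len_ms / hop_frac : analysis frame length and hop as a fraction of it.
    """

    alpha: float = 0.98
    noise_from_lead_s: float = 1.0
    gain_floor: float = 0.05
    frame_len_ms: float = 32.0
    hop_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if not 0 <= self.gain_floor < 1:
            raise ValueError(f"gain_floor must lie in [0, 1), got {self.gain_floor}")
        if not 0 < self.hop_frac <= 1:
            raise ValueError("hop_frac must lie in (0, 1]")
        if self.frame_len_ms <= 0 or self.noise_from_lead_s < 0:
            raise ValueError("frame_len_ms must be positive, noise_from_lead_s >= 0")

    def frame_len(self, sample_rate_hz: float) -> int:
        n = int(round(sample_rate_hz * self.frame_len_ms / 1000.0))
        return max(2, n + (n % 2))  # even length for clean 50% overlap

    def hop(self, sample_rate_hz: float) -> int:
        return max(1, int(round(self.frame_len(sample_rate_hz) * self.hop_frac)))


@dataclass
class SpectralFrames:
    """One-sided short-time spectra, frequency bins x frames.

    Frame ``t`` covers input samples ``[t*hop - frame_len, t*hop)`` of the
    original (unpadded) signal; the analysis pads ``frame_len`` zeros on the
    left so early frames exist for signals starting at sample 0.
    """

    frames: np.ndarray  # complex, (frame_len//2 + 1, n_frames)
    frame_len: int
    hop: int
    window_name: str
    sample_rate_hz: float
    n_samples: int  # original signal length, for exact-length resynthesis

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.frame_len:
            raise ValueError("hop must satisfy 0 < hop <= frame_len")
        if self.frames.shape[0] != self.frame_len // 2 + 1:
            raise ValueError("one-sided bin count must equal frame_len//2 + 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def frame_span(self, t: int) -> tuple:
        """(start, end) sample indices of frame t in the original signal."""
        start = t * self.hop - self.frame_len
        return start, start + self.frame_len


@dataclass
class SnrTrack:
    snr_posteriori: np.ndarray  # (bins, frames), >= 0
    snr_priori: np.ndarray  # (bins, frames), >= 0
    noise_psd: np.ndarray  # (bins,), > 0


def _window(frames_or_len, name: str = "hann") -> np.ndarray:
    length = frames_or_len if isinstance(frames_or_len, int) else frames_or_len.frame_len
    if name != "hann":
        raise ValueError(f"unsupported window {name!r}")
    return windows.hann(length, sym=False)


def stft(rec: RawRecording, params: Optional[WienerParams] = None) -> SpectralFrames:
    """Left-aligned short-time Fourier analysis of a recording."""
    params = params or WienerParams()
    x = rec.samples
    L = params.frame_len(rec.sample_rate_hz)
    hop = params.hop(rec.sample_rate_hz)
    if x.size < L:
        raise ValueError(f"recording ({x.size} samples) shorter than one frame ({L})")
    n_frames = int(np.ceil((x.size + L) / hop)) + 1
    total = (n_frames - 1) * hop + L
    xp = np.zeros(total)
    xp[L : L + x.size] = x
    win = _window(L)
    starts = np.arange(n_frames) * hop
    mat = np.stack([xp[s : s + L] for s in starts], axis=1)
    frames = np.fft.rfft(mat * win[:, None], axis=0)
    return SpectralFrames(frames, L, hop, "hann", rec.sample_rate_hz, x.size)


def istft(sf: SpectralFrames, gains: Optional[np.ndarray] = None) -> np.ndarray:
    """Overlap-add resynthesis, optionally applying per-bin/frame gains.

    Returns exactly ``sf.n_samples`` samples; without gain modification the
    round trip reproduces the analysed signal to float rounding.
    """
    spec = sf.frames if gains is None else sf.frames * gains
    mat = np.fft.irfft(spec, n=sf.frame_len, axis=0)
    total = (sf.n_frames - 1) * sf.hop + sf.frame_len
    y = np.zeros(total)
    wsum = np.zeros(total)
    win = _window(sf.frame_len)
    for t in range(sf.n_frames):
        s = t * sf.hop
        y[s : s + sf.frame_len] += mat[:, t]
        wsum[s : s + sf.frame_len] += win
    good = wsum > 1e-8
    y[good] /= wsum[good]
    return y[sf.frame_len : sf.frame_len + sf.n_samples]


def estimate_noise_psd(sf: SpectralFrames, lead_s: float) -> np.ndarray:
    """Per-bin mean power over frames wholly inside the leading silence.

    Raises :class:`InsufficientNoiseError` when fewer than 2 frames fit.
    The estimate is floored at a machine-scale epsilon so downstream
    divisions are safe even for an all-zero lead.
    """
    lead_n = int(round(lead_s * sf.sample_rate_hz))
    keep = []
    for t in range(sf.n_frames):
        start, end = sf.frame_span(t)
        if start >= 0 and end <= lead_n:
            keep.append(t)
    if len(keep) < 2:
        raise InsufficientNoiseError(
            f"leading silence of {lead_s}s holds {len(keep)} full frames; >= 2 required"
        )
    psd = np.mean(np.abs(sf.frames[:, keep]) ** 2, axis=1)
    floor = max(float(psd.max()), 1.0) * 1e-20
    return np.maximum(psd, floor)


def wiener_gain(
    snr_priori: Union[float, np.ndarray], gain_floor: float = 0.0
) -> Union[float, np.ndarray]:
    """Wiener suppression gain ``W = SNR / (SNR + 1)``, floored.

    Monotone non-decreasing in SNR, bounded in ``[gain_floor, 1]``; reaches
    1 only in the infinite-SNR limit.
    """
    snr = np.asarray(snr_priori, dtype=np.float64)
    if np.any(snr < 0):
        raise ValueError("snr_priori must be >= 0")
    with np.errstate(invalid="ignore"):
        g = np.where(np.isinf(snr), 1.0, snr / (snr + 1.0))
    g = np.maximum(g, gain_floor)
    if np.isscalar(snr_priori) or np.ndim(snr_priori) == 0:
        return float(g)
    return g


def decision_directed_snr(
    sf: SpectralFrames, noise_psd: np.ndarray, alpha: float = 0.98
) -> SnrTrack:
    """Track a-posteriori and a-priori SNR per bin and frame.

    ``gamma(f,t) = |X(f,t)|^2 / P_noise(f)``; the a-priori SNR follows the
    decision-directed recursion (see module docstring), initialised at the
    first frame with ``max(gamma - 1, 0)``.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    noise_psd = np.asarray(noise_psd, dtype=np.float64)
    if np.any(noise_psd <= 0):
        raise ValueError("noise_psd must be strictly positive")
    post = np.abs(sf.frames) ** 2 / noise_psd[:, None]
    prio = np.empty_like(post)
    ml = np.maximum(post - 1.0, 0.0)  # maximum-likelihood instantaneous term
    prio[:, 0] = ml[:, 0]
    for t in range(1, sf.n_frames):
        g_prev = prio[:, t - 1] / (prio[:, t - 1] + 1.0)
        prio[:, t] = alpha * g_prev**2 * post[:, t - 1] + (1.0 - alpha) * ml[:, t]
    return SnrTrack(post, prio, noise_psd)


def _denoise_samples(x: np.ndarray, sample_rate_hz: float, lead_s: float,
                     params: WienerParams) -> np.ndarray:
    rec = RawRecording(x, sample_rate_hz, min(lead_s, 0.999 * x.size / sample_rate_hz))
    sf = stft(rec, params)
    if not np.any(x):
        return np.zeros_like(x)
    noise_psd = estimate_noise_psd(sf, lead_s)
    track = decision_directed_snr(sf, noise_psd, params.alpha)
    gains = wiener_gain(track.snr_priori, params.gain_floor)
    y = istft(sf, gains)
    return np.clip(y, -1.0, 1.0)


def denoise_recording(rec: RawRecording, params: Optional[WienerParams] = None) -> RawRecording:
    """Wiener-filter one recording; output preserves rate, length and lead
    annotation, with peak bounded by the input peak (gains never exceed 1)."""
    params = params or WienerParams()
    lead = params.noise_from_lead_s if params.noise_from_lead_s > 0 else rec.silence_lead_s
    y = _denoise_samples(rec.samples, rec.sample_rate_hz, lead, params)
    return RawRecording(y, rec.sample_rate_hz, rec.silence_lead_s)


class WienerDenoiser(TransformerMixin, BaseEstimator):
    """scikit-learn transformer applying Wiener denoising row-wise.

    ``X`` is ``(n_recordings, n_samples)`` at a common sample rate; each row
    is denoised independently using its own leading ``lead_s`` seconds for
    the noise estimate.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(
        self,
        sample_rate_hz: float = 22050.0,
        lead_s: float = 1.0,
        alpha: float = 0.98,
        gain_floor: float = 0.05,
        frame_len_ms: float = 32.0,
        hop_frac: float = 0.5,
    ):
        self.sample_rate_hz = sample_rate_hz
        self.lead_s = lead_s
        self.alpha = alpha
        self.gain_floor = gain_floor
        self.frame_len_ms = frame_len_ms
        self.hop_frac = hop_frac

    def _params(self) -> WienerParams:
        return WienerParams(
            alpha=self.alpha,
            noise_from_lead_s=self.lead_s,
            gain_floor=self.gain_floor,
            frame_len_ms=self.frame_len_ms,
            hop_frac=self.hop_frac,
        )

    def fit(self, X, y=None):
        self._params()  # validates
        X = check_array(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=np.float64)
        params = self._params()
        return np.stack(
            [_denoise_samples(row, self.sample_rate_hz, self.lead_s, params) for row in X]
        )
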