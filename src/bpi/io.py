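"""WAV and envelope-CSV persistence.

WAV files are RIFF PCM, 16-bit mono, read and written through
:mod:`scipy.io.wavfile`.  Envelopes are persisted as one CSV per envelope
with a ``value`` column and ``# key=value`` header comments, written with 17
significant digits so float64 values round-trip bit-exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.io import wavfile

from .core import BreathEnvelope, FormatError, RawRecording

__all__ = ["read_wav", "write_wav", "read_envelope_csv", "write_envelope_csv"]

_INT16_FULL_SCALE = 32767.0


def write_wav(path: Union[str, Path], rec: RawRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    data = np.round(np.clip(rec.samples, -1.0, 1.0) * _INT16_FULL_SCALE).astype(np.int16)
    wavfile.write(str(path), int(round(rec.sample_rate_hz)), data)


def read_wav(
    path: Union[str, Path],
    silence_lead_s: float = 1.0,
    expected_rate_hz: Optional[float] = None,
) -> RawRecording:
    """Read a mono PCM WAV into a :class:`RawRecording`.

    Integer PCM is scaled to ``[-1, 1]``; stereo input is rejected.
    """
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got shape {data.shape}")
    if expected_rate_hz is not None and rate != int(round(expected_rate_hz)):
        raise FormatError(
            f"{path}: sample rate {rate} Hz, expected {expected_rate_hz} Hz"
        )
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
    return RawRecording(samples, sample_rate_hz=float(rate), silence_lead_s=silence_lead_s)


def write_envelope_csv(path: Union[str, Path], env: BreathEnvelope) -> None:
    """Persist one envelope as CSV (header comments + a ``value`` column)."""
    label = "" if env.class_label is None else str(int(env.class_label))
    header = (
        f"# rate_hz={env.rate_hz!r}\n"
        f"# duration_s={env.duration_s!r}\n"
        f"# class_label={label}\n"
        "value"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, env.values, fmt="%.17g")


def read_envelope_csv(path: Union[str, Path]) -> BreathEnvelope:
    """Load an envelope written by :func:`write_envelope_csv`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing envelope file: {path}")
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line and line != "value":
                body.append(line)
    if "rate_hz" not in meta:
        raise FormatError(f"{path}: missing rate_hz header")
    values = np.loadtxt(_io.StringIO("\n".join(body)), dtype=np.float64, ndmin=1)
    label = meta.get("class_label", "")
    return BreathEnvelope(
        values,
        rate_hz=float(meta["rate_hz"]),
        class_label=int(label) if label else None,
    )
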