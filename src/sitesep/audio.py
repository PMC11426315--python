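"""Core audio containers and I/O.

Everything downstream operates on mono :class:`Waveform` objects at a
canonical internal rate of 22,050 Hz.  Field recorders and every pipeline
stage here are single-channel, so multichannel WAV input is averaged to
mono on read; trilateration represents each microphone as its own
Waveform.  Samples are stored as float32 in the nominal range [-1, 1]
(PCM16 input is scaled by 1/32768), indexing is 0-based and time
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical internal sampling rate in Hz.
DEFAULT_RATE = 22_050


class AudioFormatError(ValueError):
    """Raised for unreadable or unsupported audio files."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it is undefined on (e.g. silence)."""


@dataclass(frozen=True)
class TimeInterval:
    """Half-open time span ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"end_s ({self.end_s}) must exceed start_s ({self.start_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples plus a sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        if len(self.samples) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def replace_samples(self, samples: np.ndarray) -> "Waveform":
        return Waveform(samples, self.rate)


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM16 or float32/float64 WAV file as a mono Waveform.

    Multichannel files are downmixed by averaging channels.  PCM16
    values are scaled by 1/32768 to the nominal [-1, 1] range.
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises bare ValueError on malformed RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples, int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a Waveform as an IEEE float32 WAV file."""
    wavfile.write(str(path), int(w.rate), w.samples.astype(np.float32))


def resample(w: Waveform, new_rate: int) -> Waveform:
    """Band-limited polyphase resampling; duration preserved within one sample."""
    if not new_rate > 0:
        raise ValueError(f"new_rate must be positive, got {new_rate}")
    if new_rate == w.rate:
        return w
    frac = Fraction(int(new_rate), int(w.rate))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, int(new_rate))


def slice_interval(w: Waveform, iv: TimeInterval, pad: bool = False) -> Waveform:
    """Extract ``[iv.start_s, iv.end_s)``.

    With ``pad`` set, spans outside the recording are zero-filled so the
    output has exactly ``round(duration * rate)`` samples (used for the
    fixed-length buffered extraction around detected songs).  Without
    ``pad``, an interval fully outside the audio raises.
    """
    n = len(w.samples)
    i0 = int(round(iv.start_s * w.rate))
    i1 = int(round(iv.end_s * w.rate))
    if pad:
        out = np.zeros(i1 - i0, dtype=np.float64)
        lo, hi = max(i0, 0), min(i1, n)
        if hi > lo:
            out[lo - i0 : hi - i0] = w.samples[lo:hi]
        return Waveform(out, w.rate)
    if i1 <= 0 or i0 >= n:
        raise ValueError(f"interval [{iv.start_s}, {iv.end_s}) lies outside the audio")
    return Waveform(w.samples[max(i0, 0) : min(i1, n)], w.rate)


#: Distinguished level for all-zero audio.
SILENCE_DB = -np.inf


def peak_dbfs(w: Waveform) -> float:
    """Peak level 20*log10(max |sample|) in dBFS; ``-inf`` for silence."""
    if len(w.samples) == 0:
        raise ValueError("peak_dbfs is undefined on empty audio")
    peak = float(np.max(np.abs(w.samples)))
    if peak == 0.0:
        return SILENCE_DB
    return float(20.0 * np.log10(peak))
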