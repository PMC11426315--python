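"""Time-scale and pitch modification.

A classical phase vocoder provides pitch-preserving time stretching:
the STFT frame sequence is resampled along time with linear magnitude
interpolation while instantaneous phase is advanced by the accumulated,
wrapped phase-difference estimate.  Pitch shifting composes a stretch
with polyphase resampling back to the original duration, which scales
all frequencies by the semitone factor.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import ShortTimeFFT, resample_poly
from scipy.signal.windows import hann

from .audio import Waveform


def _stft_obj(rate: int, nfft: int, hop: int) -> ShortTimeFFT:
    return ShortTimeFFT(hann(nfft, sym=False), hop=hop, fs=rate, fft_mode="onesided")


def phase_vocoder(S: np.ndarray, rate_factor: float, hop: int, nfft: int) -> np.ndarray:
    """Resample an STFT along time by ``rate_factor`` (>1 speeds up)."""
    n_bins, n_frames = S.shape
    time_steps = np.arange(0, n_frames, rate_factor)
    omega = 2 * np.pi * np.arange(n_bins) * hop / nfft  # expected phase advance/frame
    out = np.empty((n_bins, len(time_steps)), dtype=complex)
    phase_acc = np.angle(S[:, 0])
    padded = np.pad(S, ((0, 0), (0, 2)))
    for k, step in enumerate(time_steps):
        i = int(step)
        frac = step - i
        mag = (1 - frac) * np.abs(padded[:, i]) + frac * np.abs(padded[:, i + 1])
        out[:, k] = mag * np.exp(1j * phase_acc)
        dphase = np.angle(padded[:, i + 1]) - np.angle(padded[:, i]) - omega
        dphase -= 2 * np.pi * np.round(dphase / (2 * np.pi))
        phase_acc = phase_acc + omega + dphase
    return out


def time_stretch(w: Waveform, factor: float, nfft: int = 1024, hop: int = 256) -> Waveform:
    """Stretch duration by ``factor`` (1.2 -> 20% longer), preserving pitch."""
    if not factor > 0:
        raise ValueError("stretch factor must be positive")
    if factor == 1.0 or len(w.samples) < nfft:
        return w
    sft = _stft_obj(w.rate, nfft, hop)
    S = sft.stft(w.samples)
    S2 = phase_vocoder(S, 1.0 / factor, hop, nfft)
    n_out = int(round(len(w.samples) * factor))
    out = np.real(sft.istft(S2, k1=n_out))
    # the resynthesis tail need not decay to zero at the truncation point;
    # a short fade keeps the clip free of broadband boundary clicks
    fade = min(int(0.005 * w.rate), len(out) // 2)
    if fade > 0:
        ramp = np.linspace(0.0, 1.0, fade)
        out[:fade] *= ramp
        out[-fade:] *= ramp[::-1]
    return Waveform(out, w.rate)


def pitch_shift(w: Waveform, semitones: float, nfft: int = 1024, hop: int = 256) -> Waveform:
    """Shift pitch by ``semitones``, preserving duration."""
    if semitones == 0.0:
        return w
    factor = 2.0 ** (semitones / 12.0)  # frequency scale
    stretched = time_stretch(w, factor, nfft=nfft, hop=hop)
    # playing the stretched signal 'factor' times faster restores duration
    # and multiplies all frequencies by 'factor'
    frac = Fraction(factor).limit_denominator(1000)
    out = resample_poly(stretched.samples, frac.denominator, frac.numerator)
    n = len(w.samples)
    if len(out) >= n:
        out = out[:n]
    else:
        out = np.pad(out, (0, n - len(out)))
    return Waveform(out, w.rate)
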