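"""The birdsong cleaning chain.

Extracted candidate clips are cleaned in three steps, in order:

1. zero-phase high-pass Butterworth filtering, removing rumble and road
   noise below the song band (default order 5, cutoff 2 kHz — below the
   warbler band);
2. peak normalization to -1 dBFS, standardising level across clips;
3. stationary spectral gating: a per-frequency noise floor is estimated
   (from a supplied noise sample or from the quietest 10% of frames),
   and time-frequency bins whose neighbourhood-smoothed magnitude stays
   below floor + threshold are attenuated by a fixed reduction.

Clips whose song is more than 10 dB quieter than the surrounding
background (birdsong-background ratio below -10 dB) are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import ShortTimeFFT, butter, sosfiltfilt
from scipy.signal.windows import hann

from .audio import DegenerateInputError, TimeInterval, Waveform, peak_dbfs

#: Screen threshold: clips with BBR below this are flagged for removal.
BBR_REMOVAL_THRESHOLD_DB = -10.0


@dataclass(frozen=True)
class CleaningConfig:
    hp_cutoff_hz: float = 2_000.0
    hp_order: int = 5
    target_peak_db: float = -1.0
    gate_nfft: int = 1024
    gate_hop: int = 256
    gate_threshold_db: float = 6.0
    gate_reduction_db: float = 30.0
    noise_floor_quantile: float = 0.10
    # detection smoothing (freq bins, time frames): large enough that pure
    # stationary noise cannot cross the threshold through sample fluctuation
    gate_detect_smooth: tuple[int, int] = (7, 9)
    gate_mask_smooth: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        if self.hp_order < 1:
            raise ValueError("hp_order must be >= 1")
        if self.gate_nfft & (self.gate_nfft - 1):
            raise ValueError("gate_nfft must be a power of two")
        if not self.gate_threshold_db > 0:
            raise ValueError("gate_threshold_db must be positive")


@dataclass(frozen=True)
class BbrEstimate:
    """Birdsong-background ratio of one clip, in dB."""

    song_db: float
    background_db: float

    @property
    def ratio_db(self) -> float:
        return self.song_db - self.background_db

    @property
    def flagged_for_removal(self) -> bool:
        return self.ratio_db < BBR_REMOVAL_THRESHOLD_DB


def highpass(w: Waveform, cfg: CleaningConfig) -> Waveform:
    """Zero-phase (forward-backward) Butterworth high-pass."""
    nyq = w.rate / 2
    if not 0 < cfg.hp_cutoff_hz < nyq:
        raise ValueError(f"cutoff {cfg.hp_cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = butter(cfg.hp_order, cfg.hp_cutoff_hz / nyq, btype="high", output="sos")
    return w.replace_samples(sosfiltfilt(sos, w.samples))


def normalize_peak(w: Waveform, target_peak_db: float = -1.0) -> Waveform:
    """Scale so the peak sample sits at ``target_peak_db`` dBFS."""
    peak = peak_dbfs(w)
    if not np.isfinite(peak):
        raise DegenerateInputError("cannot peak-normalize silent audio")
    gain = 10.0 ** ((target_peak_db - peak) / 20.0)
    return w.replace_samples(w.samples * gain)


def _stft(cfg: CleaningConfig, rate: int) -> ShortTimeFFT:
    win = hann(cfg.gate_nfft, sym=False)
    return ShortTimeFFT(win, hop=cfg.gate_hop, fs=rate, fft_mode="onesided")


def spectral_gate(
    w: Waveform, cfg: CleaningConfig = CleaningConfig(), noise_sample: Waveform | None = None
) -> Waveform:
    """Stationary spectral gating noise reduction.

    The per-frequency noise floor is the mean magnitude of the quietest
    ``noise_floor_quantile`` of frames (or all frames of
    ``noise_sample`` when given; stationarity assumed).  Magnitudes are
    smoothed over a ``gate_detect_smooth`` neighbourhood before
    comparison with floor + threshold, so noise fluctuations cannot
    punch holes in the gate while genuine signal ridges stay above it;
    the resulting soft mask is smoothed over ``gate_mask_smooth`` before
    being applied.  Output length equals input length.
    """
    if len(w.samples) < cfg.gate_nfft:
        raise ValueError(f"input shorter than one frame ({cfg.gate_nfft} samples)")
    if np.all(w.samples == 0):
        return w
    sft = _stft(cfg, w.rate)
    S = sft.stft(w.samples)
    mag = np.abs(S)
    if noise_sample is not None:
        noise_mag = np.abs(sft.stft(noise_sample.samples))
        floor = noise_mag.mean(axis=1, keepdims=True)
    else:
        frame_energy = (mag**2).sum(axis=0)
        n_quiet = max(1, int(np.ceil(cfg.noise_floor_quantile * mag.shape[1])))
        quiet = np.argsort(frame_energy, kind="stable")[:n_quiet]
        floor = mag[:, quiet].mean(axis=1, keepdims=True)
    threshold = floor * 10.0 ** (cfg.gate_threshold_db / 20.0)
    smoothed = uniform_filter(mag, size=cfg.gate_detect_smooth, mode="nearest")
    reduction = 10.0 ** (-cfg.gate_reduction_db / 20.0)
    mask = np.where(smoothed > threshold, 1.0, reduction)
    mask = uniform_filter(mask, size=cfg.gate_mask_smooth, mode="nearest")
    out = sft.istft(S * mask, k1=len(w.samples))
    return w.replace_samples(np.real(out))


def estimate_bbr(
    w: Waveform, song_iv: TimeInterval, song_band: tuple[float, float]
) -> BbrEstimate:
    """In-band mean power of the song span vs its time complement, in dB.

    Invariant to global gain (a ratio of powers in the same band).
    """
    lo, hi = song_band
    nyq = w.rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"song_band must satisfy 0 < lo < hi < Nyquist, got {song_band}")
    if song_iv.start_s < 0 or song_iv.end_s > w.duration_s + 1e-9:
        raise ValueError("song interval must lie inside the recording")
    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    banded = sosfiltfilt(sos, w.samples)
    i0 = int(round(song_iv.start_s * w.rate))
    i1 = int(round(song_iv.end_s * w.rate))
    song = banded[i0:i1]
    background = np.concatenate([banded[:i0], banded[i1:]])
    if len(background) == 0:
        raise ValueError("song interval covers the whole clip; no background to compare")
    song_db = 10.0 * np.log10(max(np.mean(song**2), 1e-300))
    bg_db = 10.0 * np.log10(max(np.mean(background**2), 1e-300))
    return BbrEstimate(song_db=float(song_db), background_db=float(bg_db))


def clean_segment(
    w: Waveform, cfg: CleaningConfig = CleaningConfig(), noise_sample: Waveform | None = None
) -> Waveform:
    """Full chain: highpass -> peak normalize -> spectral gate."""
    out = highpass(w, cfg)
    out = normalize_peak(out, cfg.target_peak_db)
    return spectral_gate(out, cfg, noise_sample=noise_sample)
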