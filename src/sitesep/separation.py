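"""Separator contract, oracle separators, and chunked inference.

A separator is any callable ``mixture -> SeparationEstimate``.  Two
reference implementations ship here:

* :class:`OracleRatioMask` — an ideal-ratio-mask separator built from
  the ground-truth stems; an upper-bound stand-in for a trained deep
  model when evaluating the rest of the pipeline.
* :func:`separate_identity` — the no-op baseline ("before separation").

Long inputs are processed in 3-s chunks advanced by 2 s (1-s overlap)
and merged with a 0.5-s linear crossfade centered in the overlap; merge
weights form an exact partition of unity, so the identity separator
run through chunking reproduces its input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .audio import Waveform


@dataclass(frozen=True)
class SeparationEstimate:
    song_est: Waveform
    background_est: Waveform


Separator = Callable[[Waveform], SeparationEstimate]


@dataclass(frozen=True)
class ChunkPlan:
    window_s: float = 3.0
    overlap_s: float = 1.0
    crossfade_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.crossfade_s <= self.overlap_s < self.window_s:
            raise ValueError("require 0 < crossfade_s <= overlap_s < window_s")


def separate_identity(mixture: Waveform) -> SeparationEstimate:
    """No-op baseline: the mixture is returned as the song estimate."""
    return SeparationEstimate(
        song_est=mixture,
        background_est=mixture.replace_samples(np.zeros_like(mixture.samples)),
    )


class OracleRatioMask:
    """Ideal-ratio-mask separator using ground-truth stems.

    Masks the mixture STFT by |S|/(|S|+|B|+eps) per source.  The stems
    must correspond to the full mixture this instance will see; chunked
    use slices the stems to match each chunk via the ``offset`` plumbing
    in :func:`chunked_separate`.
    """

    def __init__(
        self,
        true_song: Waveform,
        true_background: Waveform,
        nfft: int = 1024,
        hop: int = 256,
        eps: float = 1e-12,
    ) -> None:
        if len(true_song) != len(true_background):
            raise ValueError("stems must have equal length")
        self.true_song = true_song
        self.true_background = true_background
        self.nfft = nfft
        self.hop = hop
        self.eps = eps

    def _sft(self, rate: int) -> ShortTimeFFT:
        return ShortTimeFFT(hann(self.nfft, sym=False), hop=self.hop, fs=rate,
                            fft_mode="onesided")

    def __call__(self, mixture: Waveform, offset: int = 0) -> SeparationEstimate:
        n = len(mixture.samples)
        song = self.true_song.samples[offset : offset + n]
        bg = self.true_background.samples[offset : offset + n]
        if len(song) != n:
            raise ValueError("mixture extends past the ground-truth stems")
        sft = self._sft(mixture.rate)
        M = sft.stft(mixture.samples)
        S = np.abs(sft.stft(song))
        B = np.abs(sft.stft(bg))
        denom = S + B + self.eps
        song_est = np.real(sft.istft(M * (S / denom), k1=n))
        bg_est = np.real(sft.istft(M * (B / denom), k1=n))
        return SeparationEstimate(
            song_est=mixture.replace_samples(song_est),
            background_est=mixture.replace_samples(bg_est),
        )


def chunk_starts(n_samples: int, window: int, hop: int) -> list[int]:
    """Chunk start indices: every ``hop`` samples, plus a right-aligned tail."""
    if n_samples <= window:
        return [0]
    starts = list(range(0, n_samples - window + 1, hop))
    if starts[-1] + window < n_samples:
        starts.append(n_samples - window)
    return starts


def chunked_separate(
    mixture: Waveform, separator: Separator, plan: ChunkPlan = ChunkPlan()
) -> SeparationEstimate:
    """Run a separator over overlapping chunks and crossfade-merge.

    Chunks of ``window_s`` advance by ``window_s - overlap_s``; the
    final chunk is right-aligned to cover the tail.  In each overlap the
    new chunk fades in linearly over ``crossfade_s`` centered in the
    overlap, the outer margins coming from the earlier/later chunk
    respectively; weights sum to exactly one at every sample.  Inputs
    shorter than one window are passed through unchunked.
    """
    rate = mixture.rate
    n = len(mixture.samples)
    window = int(round(plan.window_s * rate))
    hop = window - int(round(plan.overlap_s * rate))
    fade = int(round(plan.crossfade_s * rate))
    if n <= window:
        return _call(separator, mixture, 0)

    song_out = np.zeros(n)
    bg_out = np.zeros(n)
    covered = 0  # samples [0, covered) already written
    for start in chunk_starts(n, window, hop):
        chunk = Waveform(mixture.samples[start : start + window], rate)
        est = _call(separator, chunk, start)
        s, b = est.song_est.samples, est.background_est.samples
        if covered == 0:
            song_out[:window] = s
            bg_out[:window] = b
            covered = window
            continue
        ov = covered - start  # overlap with what is already written
        w_new = np.ones(window)
        f = min(fade, ov)
        lead = (ov - f) // 2  # outer margin kept from the earlier chunk
        w_new[: lead + f] = 0.0
        w_new[lead : lead + f] = np.arange(1, f + 1) / f
        sl = slice(start, start + window)
        song_out[sl] = song_out[sl] * (1 - w_new) + s * w_new
        bg_out[sl] = bg_out[sl] * (1 - w_new) + b * w_new
        covered = start + window
    return SeparationEstimate(
        song_est=mixture.replace_samples(song_out),
        background_est=mixture.replace_samples(bg_out),
    )


def _call(separator: Separator, chunk: Waveform, offset: int) -> SeparationEstimate:
    import inspect

    target = separator.__call__ if not inspect.isfunction(separator) else separator
    try:
        accepts_offset = "offset" in inspect.signature(target).parameters
    except (TypeError, ValueError):
        accepts_offset = False
    if accepts_offset:
        return separator(chunk, offset=offset)  # type: ignore[call-arg]
    return separator(chunk)
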