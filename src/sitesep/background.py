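"""Background-audio mining.

Raw site recordings, with detector-positive song spans removed, are
condensed to their loudest few minutes: the loudness metric is a
one-second rolling summation of |x| (smoothing) followed by a
one-second rolling maximum (so selection is not fragmented into pieces
shorter than about two seconds), and the top ``total_s`` seconds by
that metric are extracted as a union of disjoint intervals, each at
least ``min_piece_s`` long.  The default condenses an hour to its
loudest five minutes, which strips plain white noise and keeps the
interesting interference (passing cars, voices, other species).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import maximum_filter1d

from .audio import TimeInterval, Waveform


@dataclass(frozen=True)
class LoudnessProfile:
    """Per-sample loudness metric for one recording."""

    metric: np.ndarray
    window_s: float
    rate: int


@dataclass(frozen=True)
class AudioPiece:
    """A kept span of a recording, with its original offset."""

    audio: Waveform
    offset_s: float


def _merge_intervals(ivs: list[TimeInterval]) -> list[TimeInterval]:
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda iv: iv.start_s)
    merged = [[ivs[0].start_s, ivs[0].end_s]]
    for iv in ivs[1:]:
        if iv.start_s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end_s)
        else:
            merged.append([iv.start_s, iv.end_s])
    return [TimeInterval(a, b) for a, b in merged]


def mask_positive_segments(w: Waveform, positives: list[TimeInterval]) -> list[AudioPiece]:
    """Remove detector-positive spans; return the kept pieces with offsets.

    Overlapping positive intervals are merged.  No kept sample lies
    inside any positive interval.
    """
    dur = w.duration_s
    merged = _merge_intervals(
        [TimeInterval(max(iv.start_s, 0.0), min(iv.end_s, dur)) for iv in positives
         if iv.end_s > 0 and iv.start_s < dur]
    )
    pieces: list[AudioPiece] = []
    cursor = 0.0
    for iv in merged:
        if iv.start_s > cursor:
            pieces.append(
                AudioPiece(slice_or_empty(w, cursor, iv.start_s), offset_s=cursor)
            )
        cursor = iv.end_s
    if cursor < dur:
        pieces.append(AudioPiece(slice_or_empty(w, cursor, dur), offset_s=cursor))
    return [p for p in pieces if len(p.audio) > 0]


def slice_or_empty(w: Waveform, start_s: float, end_s: float) -> Waveform:
    i0 = int(round(start_s * w.rate))
    i1 = int(round(end_s * w.rate))
    return Waveform(w.samples[i0:i1], w.rate)


def loudness_profile(w: Waveform, window_s: float = 1.0) -> LoudnessProfile:
    """Rolling-max of rolling-sum of |samples|, centered, edge-truncated."""
    if len(w.samples) == 0:
        raise ValueError("loudness_profile is undefined on empty audio")
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    win = max(1, int(round(window_s * w.rate)))
    absx = np.abs(w.samples)
    # centered rolling sum; zero padding == truncation for a sum
    rolled = np.convolve(absx, np.ones(win), mode="same")
    # centered rolling max; zero padding == truncation for nonnegative input
    metric = maximum_filter1d(rolled, size=win, mode="constant", cval=0.0)
    return LoudnessProfile(metric=metric, window_s=window_s, rate=w.rate)


def top_loudest(
    w: Waveform,
    profile: LoudnessProfile,
    total_s: float = 300.0,
    min_piece_s: float = 2.0,
) -> list[TimeInterval]:
    """Intervals covering the loudest ``total_s`` seconds of the recording.

    Samples are taken greedily in decreasing metric order (ties broken
    by earlier time), runs of selected samples are merged into
    intervals, pieces shorter than ``min_piece_s`` are discarded and
    selection continues until the total duration is met.  Returned
    intervals are disjoint and sorted.
    """
    n = len(w.samples)
    rate = w.rate
    if total_s > w.duration_s:
        warnings.warn("total_s exceeds recording duration; returning the whole recording")
        return [TimeInterval(0.0, w.duration_s)]
    target = int(round(total_s * rate))
    min_run = int(round(min_piece_s * rate))
    order = np.lexsort((np.arange(n), -profile.metric))
    selected = np.zeros(n, dtype=bool)
    pos = 0
    kept_count = 0
    max_rounds = 50
    for _ in range(max_rounds):
        need = target - kept_count
        if need <= 0:
            break
        taken = 0
        while pos < n and taken < need:
            i = order[pos]
            pos += 1
            if not selected[i]:
                selected[i] = True
                taken += 1
        if taken == 0:
            break
        runs = _runs(selected)
        # drop short runs from the selection so refill can proceed
        kept_count = 0
        for a, b in runs:
            if b - a < min_run:
                selected[a:b] = False
            else:
                kept_count += b - a
    runs = [(a, b) for a, b in _runs(selected) if b - a >= min_run]
    return [TimeInterval(a / rate, b / rate) for a, b in runs]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))
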