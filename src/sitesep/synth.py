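"""Parametric fixtures: warbler-like songs, site-like backgrounds, detector scores.

The Golden-cheeked Warbler sings two common song types.  A songs are a
series of repeated frequency-modulated elements followed by a buzz and an
optional trailing hook; B songs open with a buzz, optionally insert a
short note, continue with a main buzz and may end in an upward flourish.
The synthesizer is deliberately schematic — FM sweeps and amplitude-
modulated buzzes with controllable peak frequency and durations — because
downstream tests need known band edges, timing and repeat counts, not
vocal realism.  Every generator is deterministic given its seed, and the
ground-truth features of each rendered song are computable from its spec
alone (:func:`song_ground_truth`).

Backgrounds are colored noise (power ~ 1/f^alpha) plus optional tonal
interferers, low-frequency rumble and Poisson-scheduled transients,
standing in for road noise and non-target species at a recording site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .audio import DEFAULT_RATE, TimeInterval, Waveform


@dataclass(frozen=True)
class SongSpec:
    """Parameters of one schematic warbler song."""

    song_type: str = "A"  # "A" or "B"
    n_repeats: int = 4
    element_dur_s: float = 0.18
    buzz_dur_s: float = 0.5
    peak_freq_hz: float = 5_000.0
    has_hook: bool = True
    has_flourish: bool = False
    initial_buzz_dur_s: float = 0.4
    amplitude: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.song_type not in ("A", "B"):
            raise ValueError(f"song_type must be 'A' or 'B', got {self.song_type!r}")
        if self.n_repeats < 0 or self.element_dur_s < 0 or self.buzz_dur_s < 0:
            raise ValueError("durations and repeat count must be nonnegative")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")


@dataclass(frozen=True)
class SongTruth:
    """Ground-truth features of a synthesized song, derived from its spec."""

    f_min_hz: float
    f_max_hz: float
    duration_s: float
    n_repeats: int
    buzz_dur_s: float
    peak_freq_hz: float
    song_type: str


# Frequency extents of each component, as multiples of peak_freq_hz.
_ELEM_LO, _ELEM_HI = 0.85, 1.10  # FM element down-sweep
_HOOK_LO, _HOOK_HI = 1.00, 1.25  # trailing hook up-sweep
_IBUZZ = 0.90                    # B-song initial buzz carrier
_FLOURISH_HI = 1.30              # B-song flourish top
_HOOK_DUR_S = 0.15
_NOTE_DUR_S = 0.10
_FLOURISH_DUR_S = 0.20
_BUZZ_AM_HZ = 70.0
_BUZZ_AM_DEPTH = 0.55


def _segments(spec: SongSpec) -> list[tuple[str, float, float, float]]:
    """(kind, duration, f_lo, f_hi) per component, in temporal order."""
    p = spec.peak_freq_hz
    segs: list[tuple[str, float, float, float]] = []
    if spec.song_type == "A":
        for _ in range(spec.n_repeats):
            segs.append(("element", spec.element_dur_s, _ELEM_LO * p, _ELEM_HI * p))
        if spec.buzz_dur_s > 0:
            segs.append(("buzz", spec.buzz_dur_s, p, p))
        if spec.has_hook:
            segs.append(("hook", _HOOK_DUR_S, _HOOK_LO * p, _HOOK_HI * p))
    else:
        if spec.initial_buzz_dur_s > 0:
            segs.append(("buzz", spec.initial_buzz_dur_s, _IBUZZ * p, _IBUZZ * p))
        segs.append(("note", _NOTE_DUR_S, p, p))
        if spec.buzz_dur_s > 0:
            segs.append(("buzz", spec.buzz_dur_s, p, p))
        if spec.has_flourish:
            segs.append(("flourish", _FLOURISH_DUR_S, p, _FLOURISH_HI * p))
    return [s for s in segs if s[1] > 0]


def song_ground_truth(spec: SongSpec) -> SongTruth:
    """Band edges and durations implied by the spec (no audio rendered).

    Band edges are the min/max instantaneous frequencies over all
    components; the buzz AM sidebands extend them by the AM rate.
    """
    segs = _segments(spec)
    if not segs:
        raise ValueError("song spec has zero total duration")
    f_lo = min(s[2] for s in segs)
    f_hi = max(s[3] for s in segs)
    has_buzz = any(s[0] == "buzz" for s in segs)
    if has_buzz:
        f_lo = min(f_lo, min(s[2] for s in segs if s[0] == "buzz") - _BUZZ_AM_HZ)
        f_hi = max(f_hi, max(s[3] for s in segs if s[0] == "buzz") + _BUZZ_AM_HZ)
    return SongTruth(
        f_min_hz=f_lo,
        f_max_hz=f_hi,
        duration_s=sum(s[1] for s in segs),
        n_repeats=spec.n_repeats if spec.song_type == "A" else 0,
        buzz_dur_s=spec.buzz_dur_s,
        peak_freq_hz=spec.peak_freq_hz,
        song_type=spec.song_type,
    )


def _fm_sweep(f0: float, f1: float, dur_s: float, rate: int, amp: float) -> np.ndarray:
    """Linear sweep f0 -> f1 over 70% of the duration, then a hold at f1.

    The hold gives the extreme frequency real dwell time (and hence a
    clear spectrogram ridge) instead of being a single grazed instant;
    a light Tukey taper avoids clicks without silencing the endpoints.
    """
    from scipy.signal.windows import tukey

    n = int(round(dur_s * rate))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / rate
    t_sweep = 0.7 * dur_s
    inst = np.where(t < t_sweep, f0 + (f1 - f0) * t / max(t_sweep, 1e-12), f1)
    phase = 2 * np.pi * np.cumsum(inst) / rate
    env = tukey(max(n, 2), 0.2)[:n]
    return amp * env * np.sin(phase)


def _buzz(freq: float, dur_s: float, rate: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate
    phi = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * freq * t + phi)
    am = 1.0 - _BUZZ_AM_DEPTH * 0.5 * (1 - np.cos(2 * np.pi * _BUZZ_AM_HZ * t))
    env = np.ones(n)
    edge = min(int(0.02 * rate), n // 2)
    if edge > 0:
        ramp = np.hanning(2 * edge)
        env[:edge] = ramp[:edge]
        env[-edge:] = ramp[edge:]
    return amp * env * am * carrier


def synth_song(spec: SongSpec, rate: int = DEFAULT_RATE) -> Waveform:
    """Render a schematic A or B song; deterministic given ``spec.seed``."""
    if spec.peak_freq_hz >= rate / 2:
        raise ValueError("peak_freq_hz must be below Nyquist")
    segs = _segments(spec)
    if not segs:
        raise ValueError("song spec has zero total duration")
    rng = np.random.default_rng(spec.seed)
    parts: list[np.ndarray] = []
    for kind, dur, f_lo, f_hi in segs:
        if kind == "element":
            # trailing 0.02 s of the element budget is an inter-element gap
            gap = min(0.02, 0.2 * dur)
            parts.append(_fm_sweep(f_hi, f_lo, dur - gap, rate, 0.6))
            parts.append(np.zeros(int(round(gap * rate))))
        elif kind == "buzz":
            parts.append(_buzz(f_lo, dur, rate, 1.0, rng))
        elif kind == "note":
            parts.append(_fm_sweep(f_lo, f_hi, dur, rate, 0.5))
        elif kind == "hook":
            parts.append(_fm_sweep(f_lo, f_hi, dur, rate, 0.6))
        elif kind == "flourish":
            parts.append(_fm_sweep(f_lo, f_hi, dur, rate, 0.6))
    x = np.concatenate(parts) if parts else np.zeros(0)
    # trim the inter-element gap appended after the final element
    total = int(round(sum(s[1] for s in segs) * rate))
    if len(x) > total:
        x = x[:total]
    elif len(x) < total:
        x = np.pad(x, (0, total - len(x)))
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (spec.amplitude / peak)
    return Waveform(x, rate)


@dataclass(frozen=True)
class BackgroundSpec:
    """Parameters of one synthetic site background."""

    duration_s: float = 60.0
    noise_color_exponent: float = 1.0
    tonal_components: tuple = ()
    transient_rate_per_min: float = 2.0
    low_freq_rumble_level_db: float = -20.0
    lowpass_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


def _colored_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^alpha, unit RMS."""
    white = rng.standard_normal(n)
    if alpha == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def synth_background(spec: BackgroundSpec, rate: int = DEFAULT_RATE) -> Waveform:
    """Render a site-like background; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * rate))
    x = _colored_noise(n, spec.noise_color_exponent, rng) * 0.05
    for freq, level_db in spec.tonal_components:
        amp = 10.0 ** (level_db / 20.0)
        phi = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * freq * np.arange(n) / rate + phi)
    if spec.low_freq_rumble_level_db > -np.inf:
        amp = 10.0 ** (spec.low_freq_rumble_level_db / 20.0)
        sos = butter(4, 150.0 / (rate / 2), btype="low", output="sos")
        rumble = sosfilt(sos, rng.standard_normal(n))
        rumble /= max(np.std(rumble), 1e-12)
        x += amp * rumble
    n_trans = rng.poisson(spec.transient_rate_per_min * spec.duration_s / 60.0)
    for _ in range(n_trans):
        t0 = rng.uniform(0, spec.duration_s)
        dur = rng.uniform(0.02, 0.1)
        i0, i1 = int(t0 * rate), min(int((t0 + dur) * rate), n)
        if i1 > i0:
            burst = rng.standard_normal(i1 - i0) * 0.2
            burst *= np.hanning(max(i1 - i0, 2))[: i1 - i0]
            x[i0:i1] += burst
    if spec.lowpass_hz is not None:
        sos = butter(8, spec.lowpass_hz / (rate / 2), btype="low", output="sos")
        x = sosfilt(sos, x)
    peak = np.max(np.abs(x))
    if peak > 0.95:
        x = x * (0.95 / peak)
    return Waveform(x, rate)


def count_transients(spec: BackgroundSpec) -> int:
    """Number of transient events the seeded generator will place (Poisson draw)."""
    rng = np.random.default_rng(spec.seed)
    return int(rng.poisson(spec.transient_rate_per_min * spec.duration_s / 60.0))


def synth_score_table(
    truth: list[tuple[TimeInterval, bool]],
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    window_len_s: float = 3.0,
    stride_s: float = 1.0,
    high: float = 0.9,
    low: float = 0.05,
    other_classes: tuple[str, ...] = ("noise",),
    other_level: float = 0.1,
):
    """Emulated detector outputs: one WindowScores per sliding window.

    Windows of ``window_len_s`` advance by ``stride_s``.  The target
    probability is ``high`` when the window overlaps a target interval,
    ``low`` otherwise; Gaussian jitter of ``noise_sd`` is added and the
    result clipped to [0, 1].
    """
    from .selection import WindowScores

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out: list[WindowScores] = []
    start = 0.0
    while start + window_len_s <= duration_s + 1e-9:
        win = TimeInterval(start, start + window_len_s)
        is_target = any(
            flag and iv.start_s < win.end_s and win.start_s < iv.end_s for iv, flag in truth
        )
        p = high if is_target else low
        p = float(np.clip(p + rng.normal(0, noise_sd) if noise_sd > 0 else p, 0.0, 1.0))
        others = {
            name: float(np.clip(other_level + (rng.normal(0, noise_sd) if noise_sd > 0 else 0), 0, 1))
            for name in other_classes
        }
        out.append(WindowScores(start, window_len_s, p, others))
        start += stride_s
    return out
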