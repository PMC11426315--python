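"""The mixture data generator.

Training examples are built by randomly stitching background pieces
into a bed of the requested duration and layering augmented songs on
top.  Backgrounds are never layered on each other (one site ambience at
a time keeps the level realistic); songs are time-stretched by -20..+20%,
gained by a factor in [0.15, 1.2] (i.e. amplified by -85%..+20%),
pitch-shifted within +-1 semitone by default, and placed at uniform
random offsets with overlaps permitted.  The background is occasionally
attenuated hard (x0.1 with probability 0.05, x0.05 with probability
0.05) so a trained model also sees near-clean songs.  When a target
birdsong-background ratio is requested the song stem is rescaled so
RMS(songs)/RMS(background) hits it exactly; the standard evaluation
grid is {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1, 1.5, 2}.

The mixture is formed as ``song_stem + background_stem`` — exact float
addition, never re-derived — so stem additivity holds to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import TimeInterval, Waveform
from .effects import pitch_shift, time_stretch

#: Evaluation grid of birdsong-background ratios.
RATIO_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0)

CROSSFADE_S = 0.05


@dataclass(frozen=True)
class AugmentationRanges:
    time_stretch: tuple[float, float] = (0.8, 1.2)
    gain: tuple[float, float] = (0.15, 1.2)
    pitch_shift_semitones: tuple[float, float] = (-1.0, 1.0)
    bg_attenuation_schedule: tuple[tuple[float, float], ...] = ((0.1, 0.05), (0.05, 0.05))

    def __post_init__(self) -> None:
        for lo, hi in (self.time_stretch, self.gain, self.pitch_shift_semitones):
            if lo > hi:
                raise ValueError("range endpoints must be ordered")
        if sum(p for _, p in self.bg_attenuation_schedule) > 1.0 + 1e-12:
            raise ValueError("attenuation probabilities must sum to at most 1")


IDENTITY_RANGES = AugmentationRanges(
    time_stretch=(1.0, 1.0), gain=(1.0, 1.0), pitch_shift_semitones=(0.0, 0.0),
    bg_attenuation_schedule=(),
)


@dataclass(frozen=True)
class MixSpec:
    duration_s: float = 60.0
    songs_per_min: float = 6.0
    target_ratio: float | None = None
    class_weights: dict = field(default_factory=dict)
    seed: int = 0
    fixed_song_count: int | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.songs_per_min < 0:
            raise ValueError("songs_per_min must be nonnegative")
        if any(wt < 0 for wt in self.class_weights.values()):
            raise ValueError("class weights must be nonnegative")


@dataclass(frozen=True)
class PlacedEvent:
    song_index: int
    song_class: str
    interval: TimeInterval
    stretch: float
    gain: float
    pitch_semitones: float


@dataclass(frozen=True)
class MixtureExample:
    mixture: Waveform
    song_stem: Waveform
    background_stem: Waveform
    events: list[PlacedEvent]
    realized_ratio: float


def stitch_background(bank: list[Waveform], duration_s: float, seed: int = 0) -> Waveform:
    """Concatenate random bank pieces with short crossfades to ``duration_s``.

    Joins use an amplitude-complementary (linear) 50 ms crossfade, so
    every output sample is a convex combination of bank samples.  A
    single long piece yields a random contiguous excerpt.
    """
    if not bank:
        raise ValueError("background bank is empty")
    rate = bank[0].rate
    n_target = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    fade = int(round(CROSSFADE_S * rate))
    out = np.zeros(0)
    while len(out) < n_target:
        piece = bank[rng.integers(len(bank))].samples
        if len(out) == 0:
            # random excerpt if the piece alone can cover the target
            if len(piece) > n_target:
                start = rng.integers(len(piece) - n_target + 1)
                piece = piece[start : start + n_target]
            out = piece.copy()
            continue
        f = min(fade, len(out), len(piece))
        if f > 0:
            ramp = np.linspace(0.0, 1.0, f, endpoint=False)
            joined = out[-f:] * (1 - ramp) + piece[:f] * ramp
            out = np.concatenate([out[:-f], joined, piece[f:]])
        else:
            out = np.concatenate([out, piece])
    return Waveform(out[:n_target], rate)


def augment_song(
    song: Waveform, ranges: AugmentationRanges = AugmentationRanges(), seed: int = 0
) -> tuple[Waveform, dict]:
    """Random stretch (pitch-preserving), pitch shift, and gain; params returned."""
    rng = np.random.default_rng(seed)
    stretch = float(rng.uniform(*ranges.time_stretch))
    semitones = float(rng.uniform(*ranges.pitch_shift_semitones))
    gain = float(rng.uniform(*ranges.gain))
    out = song
    if stretch != 1.0:
        out = time_stretch(out, stretch)
    if semitones != 0.0:
        out = pitch_shift(out, semitones)
    out = out.replace_samples(out.samples * gain)
    return out, {"stretch": stretch, "gain": gain, "pitch_semitones": semitones}


def realized_ratio(song_stem: Waveform, background_stem: Waveform) -> float:
    """Total-volume ratio of the stems, volume taken as RMS."""
    bg_rms = background_stem.rms()
    if bg_rms == 0.0:
        raise ValueError("realized_ratio undefined for a silent background stem")
    return song_stem.rms() / bg_rms


def _draw_class(weights: dict, classes: list[str], rng: np.random.Generator) -> str:
    if not weights:
        return classes[int(rng.integers(len(classes)))]
    names = sorted(weights)
    w = np.array([weights[c] for c in names], dtype=float)
    w /= w.sum()
    return names[int(rng.choice(len(names), p=w))]


def generate_example(
    song_bank: list[tuple[Waveform, str]],
    bg_bank: list[Waveform],
    spec: MixSpec = MixSpec(),
    ranges: AugmentationRanges = AugmentationRanges(),
) -> MixtureExample:
    """Build one (mixture, stems, manifest) example.

    Song count is Poisson at ``songs_per_min`` (or ``fixed_song_count``
    for the ratio experiments); songs drawn by class weight, augmented,
    placed uniformly with overlap allowed.  Songs longer than the
    mixture are skipped with a warning.
    """
    if not song_bank or not bg_bank:
        raise ValueError("song and background banks must be nonempty")
    rng = np.random.default_rng(spec.seed)
    rate = bg_bank[0].rate
    background = stitch_background(bg_bank, spec.duration_s, seed=int(rng.integers(2**31)))
    # background attenuation schedule: one draw per example, whole stem
    u = rng.uniform()
    acc = 0.0
    bg_gain = 1.0
    for gain_factor, prob in ranges.bg_attenuation_schedule:
        acc += prob
        if u < acc:
            bg_gain = gain_factor
            break
    background = background.replace_samples(background.samples * bg_gain)

    n_samples = len(background.samples)
    if spec.fixed_song_count is not None:
        n_songs = spec.fixed_song_count
    else:
        n_songs = int(rng.poisson(spec.songs_per_min * spec.duration_s / 60.0))
    classes = sorted({c for _, c in song_bank})
    by_class: dict[str, list[int]] = {c: [] for c in classes}
    for i, (_, c) in enumerate(song_bank):
        by_class[c].append(i)

    song_stem = np.zeros(n_samples)
    events: list[PlacedEvent] = []
    import warnings

    for _ in range(n_songs):
        cls = _draw_class(spec.class_weights, classes, rng)
        idx = by_class[cls][int(rng.integers(len(by_class[cls])))]
        song, _ = song_bank[idx]
        aug, params = augment_song(song, ranges, seed=int(rng.integers(2**31)))
        if len(aug.samples) > n_samples:
            warnings.warn("augmented song longer than mixture; skipped")
            continue
        start = int(rng.integers(n_samples - len(aug.samples) + 1))
        song_stem[start : start + len(aug.samples)] += aug.samples
        events.append(
            PlacedEvent(
                song_index=idx,
                song_class=cls,
                interval=TimeInterval(start / rate, (start + len(aug.samples)) / rate),
                stretch=params["stretch"],
                gain=params["gain"],
                pitch_semitones=params["pitch_semitones"],
            )
        )

    if spec.target_ratio is not None and np.any(song_stem != 0):
        current = realized_ratio(Waveform(song_stem, rate), background)
        song_stem *= spec.target_ratio / current
    song_wf = Waveform(song_stem, rate)
    mixture = Waveform(song_stem + background.samples, rate)
    ratio = realized_ratio(song_wf, background) if np.any(song_stem != 0) else 0.0
    return MixtureExample(
        mixture=mixture,
        song_stem=song_wf,
        background_stem=background,
        events=events,
        realized_ratio=ratio,
    )
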