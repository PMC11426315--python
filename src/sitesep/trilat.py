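"""Trilateration simulation.

Three microphones 1.5 m above the ground — one at the origin, one 10 m
north, one 10 m east — record a song rendered through per-microphone
forest impulse responses; identical, unconvolved background audio is
layered on every channel (interference arriving with no usable delay
structure, the worst case for correlation-based timing).  Time
differences of arrival (TDOA) are the integer-sample cross-correlation
lags against the reference channel, and the source position follows by
solving the pair of hyperbolic TDOA equations in the microphone plane
(coarse grid search, then Gauss-Newton refinement).

The forest impulse response is a simplified single-scatter model: a
direct tap at distance/c with 1/distance amplitude decay, plus up to
``max_echoes`` echo taps routed via randomly placed trees, each delayed
by the two-leg path and attenuated by both legs and a scattering loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .audio import Waveform
from .metrics import normal_ci90, xcorr_lag
from .separation import ChunkPlan, OracleRatioMask, chunked_separate

#: The three-microphone array geometry used throughout (meters).
DEFAULT_MIC_HEIGHT_M = 1.5
SPEED_OF_SOUND = 343.0


@dataclass(frozen=True)
class MicArray:
    positions: tuple = (
        (0.0, 0.0, DEFAULT_MIC_HEIGHT_M),
        (0.0, 10.0, DEFAULT_MIC_HEIGHT_M),   # 10 m north
        (10.0, 0.0, DEFAULT_MIC_HEIGHT_M),   # 10 m east
    )
    speed_of_sound: float = SPEED_OF_SOUND

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError("need at least 3 microphones")
        if len({tuple(p) for p in self.positions}) != len(self.positions):
            raise ValueError("microphone positions must be distinct")


@dataclass(frozen=True)
class ForestIrConfig:
    n_trees: int = 0
    area_m: float = 50.0
    scatter_loss: float = 0.3
    max_echoes: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be nonnegative")
        if not 0 < self.scatter_loss < 1:
            raise ValueError("scatter_loss must lie in (0, 1)")


@dataclass(frozen=True)
class TrilatTrial:
    true_position: tuple[float, float]
    estimated_position: tuple[float, float]
    ratio: float
    separated: bool
    converged: bool = True

    @property
    def error_m(self) -> float:
        return float(np.hypot(
            self.true_position[0] - self.estimated_position[0],
            self.true_position[1] - self.estimated_position[1],
        ))


def simulate_forest_ir(
    source: tuple[float, float, float],
    mic: tuple[float, float, float],
    cfg: ForestIrConfig = ForestIrConfig(),
    rate: int = 22_050,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> Waveform:
    """Single-scatter forest impulse response from source to microphone.

    Direct tap at delay d/c with amplitude 1/max(d, 1 m); each sampled
    tree contributes a tap at (d1+d2)/c with amplitude
    scatter_loss / (max(d1,1) * max(d2,1)).  The first nonzero tap is
    always the direct path (echoes travel farther).
    """
    src = np.asarray(source, dtype=float)
    m = np.asarray(mic, dtype=float)
    d = float(np.linalg.norm(src - m))
    if d == 0.0:
        raise ValueError("source and microphone positions coincide")
    rng = np.random.default_rng(cfg.seed)
    delays = [d / speed_of_sound]
    amps = [1.0 / max(d, 1.0)]
    n_echo = min(cfg.n_trees, cfg.max_echoes)
    if n_echo > 0:
        trees = np.column_stack([
            rng.uniform(-cfg.area_m, cfg.area_m, n_echo),
            rng.uniform(-cfg.area_m, cfg.area_m, n_echo),
            np.full(n_echo, src[2]),
        ])
        d1 = np.linalg.norm(trees - src, axis=1)
        d2 = np.linalg.norm(trees - m, axis=1)
        ok = (d1 > 0) & (d2 > 0)
        delays.extend(((d1[ok] + d2[ok]) / speed_of_sound).tolist())
        amps.extend((cfg.scatter_loss / (np.maximum(d1[ok], 1.0) * np.maximum(d2[ok], 1.0))).tolist())
    n = int(np.ceil(max(delays) * rate)) + 1
    ir = np.zeros(n)
    for t, a in zip(delays, amps):
        ir[int(round(t * rate))] += a
    return Waveform(ir, rate)


def render_scene(
    song: Waveform,
    background: Waveform | None,
    bird_pos: tuple[float, float],
    mics: MicArray = MicArray(),
    cfg: ForestIrConfig = ForestIrConfig(),
    ratio: float | None = None,
    seed: int = 0,
) -> tuple[list[Waveform], list[Waveform]]:
    """Per-microphone channels and their clean song components.

    The song is convolved with each microphone's impulse response; the
    identical, unconvolved background is added to every channel, scaled
    so the song-to-background RMS ratio on channel 0 equals ``ratio``.
    Returns ``(channels, song_components)`` sharing a common length.
    """
    src = (bird_pos[0], bird_pos[1], mics.positions[0][2])
    comps = []
    for i, mic in enumerate(mics.positions):
        ir_cfg = ForestIrConfig(
            n_trees=cfg.n_trees, area_m=cfg.area_m, scatter_loss=cfg.scatter_loss,
            max_echoes=cfg.max_echoes, seed=cfg.seed,  # same forest for every mic
        )
        ir = simulate_forest_ir(src, mic, ir_cfg, song.rate, mics.speed_of_sound)
        comps.append(fftconvolve(song.samples, ir.samples))
    n = max(len(c) for c in comps)
    if background is not None:
        n = max(n, len(background.samples))
    comps = [np.pad(c, (0, n - len(c))) for c in comps]
    song_components = [Waveform(c, song.rate) for c in comps]
    if background is None:
        return [Waveform(c.copy(), song.rate) for c in comps], song_components
    bg = np.pad(background.samples, (0, n - len(background.samples)))
    bg_rms = float(np.sqrt(np.mean(bg**2)))
    if ratio is not None and bg_rms > 0:
        ch0_rms = float(np.sqrt(np.mean(comps[0] ** 2)))
        bg = bg * (ch0_rms / (ratio * bg_rms))
    channels = [Waveform(c + bg, song.rate) for c in comps]
    return channels, song_components


def estimate_tdoas(channels: list[Waveform], reference_index: int = 0) -> list[float]:
    """Cross-correlation TDOA (seconds) of each non-reference channel."""
    if len(channels) < 2:
        raise ValueError("need at least two channels")
    ref = channels[reference_index]
    return [
        xcorr_lag(ref, ch) for i, ch in enumerate(channels) if i != reference_index
    ]


def true_tdoas(bird_pos: tuple[float, float], mics: MicArray = MicArray()) -> list[float]:
    """Exact TDOAs for a source in the microphone plane (forward model)."""
    p = np.array([bird_pos[0], bird_pos[1], mics.positions[0][2]])
    m = np.asarray(mics.positions, dtype=float)
    d = np.linalg.norm(m - p, axis=1)
    return [float((dj - d[0]) / mics.speed_of_sound) for dj in d[1:]]


def trilaterate(
    tdoas: list[float],
    mics: MicArray = MicArray(),
    grid_halfwidth_m: float = 50.0,
    grid_step_m: float = 0.5,
) -> tuple[tuple[float, float], bool]:
    """Invert TDOAs to a source position in the microphone plane.

    Solves ||p - m_j|| - ||p - m_0|| = c * tau_j by coarse grid search
    over a +-``grid_halfwidth_m`` box followed by Gauss-Newton
    refinement; returns ``((x, y), converged)``.  With all-zero TDOAs
    and the default geometry the equidistant point (5, 5) is returned.
    """
    m = np.asarray(mics.positions, dtype=float)
    c = mics.speed_of_sound
    ranges = c * np.asarray(tdoas, dtype=float)

    def residuals(p: np.ndarray) -> np.ndarray:
        q = np.array([p[0], p[1], m[0][2]])
        d = np.linalg.norm(m - q, axis=1)
        return (d[1:] - d[0]) - ranges

    xs = np.arange(-grid_halfwidth_m, grid_halfwidth_m + grid_step_m, grid_step_m)
    X, Y = np.meshgrid(xs, xs)
    P = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, m[0][2])])
    D = np.linalg.norm(P[:, None, :] - m[None, :, :], axis=2)
    res = (D[:, 1:] - D[:, [0]]) - ranges[None, :]
    cost = (res**2).sum(axis=1)

    # With three microphones the two TDOA hyperbolas can intersect twice;
    # refine every well-separated low-cost basin and disambiguate with a
    # near-field prior (the array monitors its own neighborhood): among
    # solutions with equally small residual, prefer the one closest to
    # the array centroid.
    order = np.argsort(cost)[:200]
    seeds: list[np.ndarray] = []
    for idx in order:
        p = P[idx][:2]
        if all(np.linalg.norm(p - s) > 5.0 for s in seeds):
            seeds.append(p)
        if len(seeds) >= 4:
            break
    centroid = m[:, :2].mean(axis=0)
    candidates = []
    for s in seeds:
        sol = least_squares(residuals, s, method="lm")
        if sol.success:
            candidates.append((float(sol.cost), sol.x))
    if not candidates:
        best = P[np.argmin(cost)][:2]
        return (float(best[0]), float(best[1])), False
    min_cost = min(c for c, _ in candidates)
    tol = max(min_cost * 4.0, 1e-6)
    viable = [p for c, p in candidates if c <= tol]
    p_hat = min(viable, key=lambda p: np.linalg.norm(p - centroid))
    converged = bool(np.all(np.abs(p_hat) <= grid_halfwidth_m * 1.5))
    if not converged:
        p_hat = P[np.argmin(cost)][:2]
    return (float(p_hat[0]), float(p_hat[1])), converged


def sample_bird_position(
    rng: np.random.Generator,
    mics: MicArray = MicArray(),
    box_halfwidth_m: float = 20.0,
    max_range_m: float = 10.0,
) -> tuple[float, float]:
    """Uniform position within ``max_range_m`` of at least one microphone."""
    m = np.asarray(mics.positions, dtype=float)[:, :2]
    while True:
        p = rng.uniform(-box_halfwidth_m, box_halfwidth_m, 2)
        if np.min(np.linalg.norm(m - p, axis=1)) <= max_range_m:
            return float(p[0]), float(p[1])


def sample_well_posed_position(
    rng: np.random.Generator,
    mics: MicArray = MicArray(),
    min_mic_distance_m: float = 2.5,
) -> tuple[float, float]:
    """Uniform position in the array's well-posed interior.

    Samples the bounding box spanned by the microphones, excluding a
    disk around each sensor: near a microphone the two TDOA hyperbolas
    become tangent and the inversion degenerates, and outside the array
    a mirror ghost with identical TDOAs can exist.  Inside this region
    exact-TDOA inversion is unique.
    """
    m = np.asarray(mics.positions, dtype=float)[:, :2]
    lo, hi = m.min(axis=0), m.max(axis=0)
    while True:
        p = rng.uniform(lo, hi)
        if np.min(np.linalg.norm(m - p, axis=1)) >= min_mic_distance_m:
            return float(p[0]), float(p[1])


def run_trials(
    n: int,
    song_factory,
    background_factory,
    mics: MicArray = MicArray(),
    cfg: ForestIrConfig = ForestIrConfig(),
    ratio_grid: tuple[float, ...] = (0.05,),
    separate: bool = False,
    seed: int = 0,
    plan: ChunkPlan = ChunkPlan(),
) -> tuple[list[TrilatTrial], pd.DataFrame]:
    """Monte-Carlo trilateration trials, optionally with oracle separation.

    Per trial a bird position is sampled within 10 m of some microphone,
    a scene is rendered at a ratio drawn from the grid, the channels are
    (optionally) separated with a ground-truth ratio-mask separator run
    through chunked inference, TDOAs are estimated and the position
    solved.  ``song_factory(rng)`` / ``background_factory(rng)`` supply
    per-trial audio.  Returns the trials and a per-ratio summary (mean
    absolute error with 90% CI, percent of trials within 1 m).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    trials: list[TrilatTrial] = []
    for k in range(n):
        ratio = float(ratio_grid[k % len(ratio_grid)])
        bird = sample_bird_position(rng, mics)
        song = song_factory(rng)
        background = background_factory(rng)
        trial_cfg = ForestIrConfig(
            n_trees=cfg.n_trees, area_m=cfg.area_m, scatter_loss=cfg.scatter_loss,
            max_echoes=cfg.max_echoes, seed=int(rng.integers(2**31)),
        )
        channels, song_comps = render_scene(
            song, background, bird, mics, trial_cfg, ratio=ratio,
        )
        if separate:
            used = []
            for ch, comp in zip(channels, song_comps):
                bg_comp = ch.replace_samples(ch.samples - comp.samples)
                sep = OracleRatioMask(comp, bg_comp)
                used.append(chunked_separate(ch, sep, plan).song_est)
        else:
            used = channels
        tdoas = estimate_tdoas(used, reference_index=0)
        est, converged = trilaterate(tdoas, mics)
        trials.append(TrilatTrial(bird, est, ratio=ratio, separated=separate,
                                  converged=converged))
    summary = summarize_trials(trials)
    return trials, summary


def summarize_trials(trials: list[TrilatTrial]) -> pd.DataFrame:
    """Per-ratio and overall mean absolute error and percent within 1 m."""
    df = pd.DataFrame(
        {"ratio": t.ratio, "error_m": t.error_m, "within_1m": t.error_m < 1.0}
        for t in trials
    )
    rows = []
    groups = [(r, g) for r, g in df.groupby("ratio")] + [("all", df)]
    for label, grp in groups:
        mean_err, half = normal_ci90(grp["error_m"])
        rows.append({
            "ratio": label,
            "mean_error_m": mean_err,
            "ci90_m": half,
            "pct_within_1m": 100.0 * grp["within_1m"].mean(),
            "n": len(grp),
        })
    return pd.DataFrame(rows)
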