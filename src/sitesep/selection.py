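"""Candidate song selection from sliding-window detector scores.

A species classifier is run externally over each recording with a 3-s
window advanced by 1 s, producing per-window, per-class probabilities.
Windows are ranked by the joint probability of containing the target
species and *not* containing any other class (class independence
assumed, so the joint is a simple product), the top-k are kept with
greedy suppression of near-duplicate starts, and each surviving window
is extracted with a 1.5-s buffer on both sides so the whole song is
captured — a 3-s window thus yields a 6-s clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import TimeInterval, Waveform, slice_interval


@dataclass(frozen=True)
class WindowScores:
    """Classifier probabilities for one sliding window of one recording."""

    window_start_s: float
    window_len_s: float = 3.0
    target_prob: float = 0.0
    other_probs: dict = field(default_factory=dict)
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not self.window_len_s > 0:
            raise ValueError("window_len_s must be positive")
        probs = [self.target_prob, *self.other_probs.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateSegment:
    """A selected window with its joint score."""

    source_id: str
    interval: TimeInterval
    joint_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.joint_score <= 1.0:
            raise ValueError("joint_score must lie in [0, 1]")


def joint_score(ws: WindowScores) -> float:
    """P(target present and no other class present), assuming independence.

    ``target_prob * prod(1 - p_other)`` over all other classes.
    """
    score = ws.target_prob
    for p in ws.other_probs.values():
        score *= 1.0 - p
    return float(score)


def rank_and_select(
    scores: list[WindowScores], k: int, min_gap_s: float = 3.0
) -> list[CandidateSegment]:
    """Top-k windows by joint score with greedy near-duplicate suppression.

    No two selected windows from the same recording start within
    ``min_gap_s`` of each other.  Ties in score are broken by earlier
    window start, then by recording id.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    ranked = sorted(
        scores,
        key=lambda ws: (-joint_score(ws), ws.window_start_s, ws.recording_id),
    )
    chosen: list[CandidateSegment] = []
    taken: dict[str, list[float]] = {}
    for ws in ranked:
        if len(chosen) >= k:
            break
        starts = taken.setdefault(ws.recording_id, [])
        if any(abs(ws.window_start_s - s) < min_gap_s for s in starts):
            continue
        starts.append(ws.window_start_s)
        chosen.append(
            CandidateSegment(
                source_id=ws.recording_id,
                interval=TimeInterval(ws.window_start_s, ws.window_start_s + ws.window_len_s),
                joint_score=joint_score(ws),
            )
        )
    return chosen


def extract_with_buffer(w: Waveform, seg: CandidateSegment, buffer_s: float = 1.5) -> Waveform:
    """Slice the segment with symmetric buffers, zero-padded at recording edges.

    Output length is exactly ``window_len + 2 * buffer_s`` seconds.
    """
    if buffer_s < 0:
        raise ValueError("buffer_s must be nonnegative")
    iv = TimeInterval(seg.interval.start_s - buffer_s, seg.interval.end_s + buffer_s)
    return slice_interval(w, iv, pad=True)


def read_score_table(path: str | Path, target_class: str) -> list[WindowScores]:
    """Load a per-window score table (CSV or JSON-lines).

    Expected columns: ``recording_id, start_s, class, prob`` — one row
    per (window, class).  Rows for ``target_class`` become the target
    probability; all other classes go into ``other_probs``.  Window
    length defaults to 3 s and can be overridden by a ``window_len_s``
    column if present.
    """
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    out: list[WindowScores] = []
    for (rec, start), grp in df.groupby(["recording_id", "start_s"], sort=True):
        target = 0.0
        others: dict[str, float] = {}
        for _, row in grp.iterrows():
            if row["class"] == target_class:
                target = float(row["prob"])
            else:
                others[str(row["class"])] = float(row["prob"])
        win_len = float(grp["window_len_s"].iloc[0]) if "window_len_s" in grp else 3.0
        out.append(WindowScores(float(start), win_len, target, others, recording_id=str(rec)))
    return out


def write_segment_manifest(segments: list[CandidateSegment], path: str | Path) -> None:
    """Emit selected segments as a CSV manifest."""
    pd.DataFrame(
        [
            {
                "recording_id": s.source_id,
                "start_s": s.interval.start_s,
                "end_s": s.interval.end_s,
                "joint_score": s.joint_score,
            }
            for s in segments
        ]
    ).to_csv(path, index=False)
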