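"""Burying-bout segmentation and ethogram statistics.

A bout is a maximal run of burying-positive frames, stored as a half-open
frame interval [start, end).  Segmentation first merges runs separated by at
most ``max_gap_s`` of negative frames, then drops runs shorter than
``min_bout_s`` (one second by default, the conventional minimum for burying
analysis).  Merge-then-drop order matters: dropping first could erase
fragments of one long bout split by single-frame classifier flicker.

Durations are computed from frame counts, not timestamps, so they cannot
drift with float time axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import LabelSeries


@dataclass(frozen=True)
class Bout:
    start_frame: int
    end_frame: int  # half-open: [start, end)
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("bout must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class BoutSet:
    bouts: list[Bout] = field(default_factory=list)
    fps: float = 25.0
    n_frames: int | None = None  # session length, if known

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BoutSet)
            and self.fps == other.fps
            and [(b.start_frame, b.end_frame) for b in self.bouts]
            == [(b.start_frame, b.end_frame) for b in other.bouts]
        )

    def durations_s(self) -> np.ndarray:
        return np.array([b.duration_s for b in self.bouts], dtype=float)

    def to_mask(self, n_frames: int | None = None) -> np.ndarray:
        """Boolean frame mask with True inside every bout."""
        if n_frames is None:
            n_frames = self.n_frames
        if n_frames is None:
            n_frames = max((b.end_frame for b in self.bouts), default=0)
        mask = np.zeros(n_frames, dtype=bool)
        for b in self.bouts:
            mask[b.start_frame : b.end_frame] = True
        return mask

    def to_frame(self, session_id: str = "session") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": session_id,
                "bout_id": np.arange(len(self.bouts), dtype=int),
                "start_frame": [b.start_frame for b in self.bouts],
                "end_frame": [b.end_frame for b in self.bouts],
                "duration_s": [b.duration_s for b in self.bouts],
            }
        )


@dataclass
class BoutSummary:
    n_bouts: int
    mean_bout_s: float
    total_burying_s: float
    empty: bool = False  # mean reported as 0 with this flag when no bouts

    def to_dict(self) -> dict:
        return {
            "n_bouts": self.n_bouts,
            "mean_bout_s": self.mean_bout_s,
            "total_burying_s": self.total_burying_s,
            "empty": self.empty,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def segment_bouts(
    labels: LabelSeries | np.ndarray,
    fps: float,
    min_bout_s: float = 1.0,
    max_gap_s: float = 0.0,
) -> BoutSet:
    """Segment a label series into burying bouts.

    Runs of positive frames separated by at most ``max_gap_s * fps`` negative
    frames are merged first; merged runs spanning fewer than
    ``min_bout_s * fps`` frames are then dropped.  At 25 fps with the default
    1-second minimum, a 24-frame run is dropped and a 25-frame run kept.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    mask = labels.mask if isinstance(labels, LabelSeries) else np.asarray(labels, dtype=bool)
    runs = _runs(mask)

    max_gap_frames = max_gap_s * fps
    if max_gap_frames > 0 and len(runs) > 1:
        merged = [runs[0]]
        for start, end in runs[1:]:
            if start - merged[-1][1] <= max_gap_frames + 1e-9:
                merged[-1] = (merged[-1][0], end)
            else:
                merged.append((start, end))
        runs = merged

    min_frames = min_bout_s * fps
    kept = [(s, e) for s, e in runs if (e - s) >= min_frames - 1e-9]
    bouts = [Bout(s, e, (e - s) / fps) for s, e in kept]
    return BoutSet(bouts=bouts, fps=fps, n_frames=len(mask))


def summarize_bouts(bouts: BoutSet, fps: float | None = None) -> BoutSummary:
    """Headline per-session statistics: count, mean duration, total time."""
    if fps is None:
        fps = bouts.fps
    durations = np.array([b.n_frames for b in bouts], dtype=float) / fps
    total = float(durations.sum())
    if len(durations) == 0:
        return BoutSummary(n_bouts=0, mean_bout_s=0.0, total_burying_s=0.0, empty=True)
    return BoutSummary(
        n_bouts=len(durations),
        mean_bout_s=total / len(durations),
        total_burying_s=total,
    )


def bout_histogram(bouts: BoutSet, bin_edges_s: np.ndarray) -> np.ndarray:
    """Bout-duration histogram with right-open bins [e_i, e_{i+1})."""
    edges = np.asarray(bin_edges_s, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    durations = bouts.durations_s()
    counts = np.zeros(len(edges) - 1, dtype=int)
    for d in durations:
        idx = np.searchsorted(edges, d, side="right") - 1
        if 0 <= idx < len(counts) and d < edges[-1]:
            counts[idx] += 1
    return counts


def cumulative_curve(
    labels: LabelSeries | np.ndarray,
    fps: float,
    bin_s: float = 60.0,
    min_bout_s: float = 1.0,
    max_gap_s: float = 0.0,
) -> np.ndarray:
    """Cumulative burying time (seconds) at the end of each time bin.

    Computed on the post-segmentation label mask, so the final value equals
    ``summarize_bouts(...).total_burying_s`` for the same parameters.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    bouts = segment_bouts(labels, fps, min_bout_s=min_bout_s, max_gap_s=max_gap_s)
    mask = bouts.to_mask()
    n = len(mask)
    frames_per_bin = bin_s * fps
    n_bins = int(np.ceil(n / frames_per_bin)) if n else 0
    per_bin = np.zeros(n_bins, dtype=float)
    for i in range(n_bins):
        lo = int(round(i * frames_per_bin))
        hi = min(int(round((i + 1) * frames_per_bin)), n)
        per_bin[i] = mask[lo:hi].sum() / fps
    return np.cumsum(per_bin)
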