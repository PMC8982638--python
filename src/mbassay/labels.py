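"""Per-frame behavior label series.

A :class:`LabelSeries` holds, for every video frame, a real-valued score and a
ternary label: burying-positive, burying-negative, or unannotated.  Label
series come from two sources — manual annotation imports and the frame
classifier — and feed bout segmentation, heatmaps and observer-agreement
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE = 1
NEGATIVE = 0
UNANNOTATED = -1

_LABEL_NAMES = {POSITIVE: "positive", NEGATIVE: "negative", UNANNOTATED: "unannotated"}
_NAME_LABELS = {v: k for k, v in _LABEL_NAMES.items()}


@dataclass
class LabelSeries:
    """Frame-aligned burying labels.

    Parameters
    ----------
    label : ndarray of int8
        Per-frame label: 1 positive, 0 negative, -1 unannotated.
    score : ndarray of float, optional
        Per-frame classifier score (ensemble margin).  Zero when the series
        comes from manual annotation.
    """

    label: np.ndarray
    score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int8)
        if self.score is None:
            self.score = np.zeros(len(self.label), dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.score) != len(self.label):
            raise ValueError("score and label lengths differ")
        bad = ~np.isin(self.label, (POSITIVE, NEGATIVE, UNANNOTATED))
        if bad.any():
            raise ValueError("labels must be in {1, 0, -1}")

    def __len__(self) -> int:
        return len(self.label)

    @property
    def mask(self) -> np.ndarray:
        """Boolean positive-frame mask (unannotated counts as negative)."""
        return self.label == POSITIVE

    @property
    def annotated(self) -> np.ndarray:
        """Boolean mask of frames carrying a definite label."""
        return self.label != UNANNOTATED

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LabelSeries":
        mask = np.asarray(mask, dtype=bool)
        return cls(label=mask.astype(np.int8))

    def complement(self) -> "LabelSeries":
        """Swap positive and negative labels; unannotated frames unchanged."""
        out = self.label.copy()
        out[self.label == POSITIVE] = NEGATIVE
        out[self.label == NEGATIVE] = POSITIVE
        return LabelSeries(label=out, score=-self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self), dtype=int),
                "score": self.score,
                "label": [_LABEL_NAMES[int(v)] for v in self.label],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabelSeries":
        labels = df["label"]
        if labels.dtype.kind in "iub":
            lab = labels.to_numpy().astype(np.int8)
        else:
            lab = np.array([_NAME_LABELS[str(v)] for v in labels], dtype=np.int8)
        score = df["score"].to_numpy(float) if "score" in df else None
        return cls(label=lab, score=score)


def labels_from_events(
    events: pd.DataFrame, n_frames: int, fps: float
) -> LabelSeries:
    """Convert a BORIS-style start/stop event table to per-frame labels.

    ``events`` needs columns ``start_s`` and ``stop_s`` (seconds); every frame
    whose time falls inside any [start, stop) interval is positive, the rest
    negative.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    t = np.arange(n_frames) / fps
    mask = np.zeros(n_frames, dtype=bool)
    for _, row in events.iterrows():
        mask |= (t >= float(row["start_s"])) & (t < float(row["stop_s"]))
    return LabelSeries.from_mask(mask)
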