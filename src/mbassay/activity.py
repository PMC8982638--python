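"""Locomotor activity and spatial burying topography.

Distance and speed are computed in centimeters from the pixel track and the
arena calibration; occupancy heatmaps split valid frames into burying and
non-burying position histograms ("burying topography"); corner preference is
the fraction of time inside the four corner squares, a thigmotaxis proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import LabelSeries
from .tracking import ArenaGeometry


@dataclass
class ActivitySummary:
    distance_cm: float
    mean_speed_cm_s: float
    frames_used: int  # number of inter-frame steps included
    n_steps_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "distance_cm": self.distance_cm,
            "mean_speed_cm_s": self.mean_speed_cm_s,
            "frames_used": self.frames_used,
            "n_steps_excluded": self.n_steps_excluded,
        }


@dataclass
class HeatmapPair:
    burying: np.ndarray
    non_burying: np.ndarray
    bin_size_px: float
    extent: ArenaGeometry


def compute_activity(
    track: pd.DataFrame,
    px_per_cm: float,
    fps: float,
    max_step_cm: float = 10.0,
) -> ActivitySummary:
    """Total path length and mean speed over consecutive valid frames.

    Steps longer than ``max_step_cm`` (physically implausible between
    consecutive frames; almost always tracking glitches) are excluded from
    the distance and counted.  Mean speed is distance over the time spanned
    by the included steps.
    """
    if px_per_cm <= 0 or fps <= 0:
        raise ValueError("px_per_cm and fps must be positive")
    valid = track["valid"].to_numpy(bool)
    if valid.sum() < 2:
        raise ValueError("need at least two valid frames")
    x = track["x_px"].to_numpy(float)[valid] / px_per_cm
    y = track["y_px"].to_numpy(float)[valid] / px_per_cm
    frame = track["frame"].to_numpy(int)[valid]
    consecutive = np.diff(frame) == 1
    steps = np.hypot(np.diff(x), np.diff(y))[consecutive]
    ok = steps <= max_step_cm
    distance = float(steps[ok].sum())
    frames_used = int(ok.sum())
    speed = distance / (frames_used / fps) if frames_used else 0.0
    return ActivitySummary(
        distance_cm=distance,
        mean_speed_cm_s=speed,
        frames_used=frames_used,
        n_steps_excluded=int((~ok).sum()),
    )


def occupancy_heatmap(
    track: pd.DataFrame,
    labels: LabelSeries,
    arena: ArenaGeometry,
    bin_size_px: float = 16.0,
) -> HeatmapPair:
    """Position histograms of burying vs non-burying valid frames.

    Counts are stored raw (render with log(1+count) if plotting).  The two
    grids together account for every valid frame.
    """
    if len(labels) != len(track):
        raise ValueError("labels and track lengths differ")
    xs, ys = arena.corner_px[:, 0], arena.corner_px[:, 1]
    x_edges = np.arange(xs.min(), xs.max() + bin_size_px, bin_size_px)
    y_edges = np.arange(ys.min(), ys.max() + bin_size_px, bin_size_px)
    valid = track["valid"].to_numpy(bool)
    x = np.clip(track["x_px"].to_numpy(float), xs.min(), xs.max() - 1e-9)
    y = np.clip(track["y_px"].to_numpy(float), ys.min(), ys.max() - 1e-9)
    bury = valid & labels.mask
    non = valid & ~labels.mask
    grid_b, _, _ = np.histogram2d(x[bury], y[bury], bins=[x_edges, y_edges])
    grid_n, _, _ = np.histogram2d(x[non], y[non], bins=[x_edges, y_edges])
    return HeatmapPair(
        burying=grid_b.astype(int),
        non_burying=grid_n.astype(int),
        bin_size_px=bin_size_px,
        extent=arena,
    )


def plot_heatmaps(pair: HeatmapPair, path) -> None:
    """Render the burying/non-burying occupancy grids to a PNG.

    Counts are displayed on a log(1 + count) scale; stored grids stay raw.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(7, 5))
    for ax, grid, title in (
        (axes[0], pair.non_burying, "non-burying"),
        (axes[1], pair.burying, "burying"),
    ):
        ax.imshow(np.log1p(grid.T), origin="upper", cmap="inferno")
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def corner_preference(
    track: pd.DataFrame,
    arena: ArenaGeometry,
    corner_frac: float = 0.25,
) -> float:
    """Fraction of valid frames inside the four corner squares.

    Each corner square has side ``corner_frac * min(arena width, height)``
    in pixels, anchored at the arena corners.
    """
    if corner_frac <= 0:
        return 0.0
    xs, ys = arena.corner_px[:, 0], arena.corner_px[:, 1]
    x0, x1, y0, y1 = xs.min(), xs.max(), ys.min(), ys.max()
    side = corner_frac * min(x1 - x0, y1 - y0)
    valid = track["valid"].to_numpy(bool)
    if not valid.any():
        return 0.0
    x = track["x_px"].to_numpy(float)[valid]
    y = track["y_px"].to_numpy(float)[valid]
    near_x = (x <= x0 + side) | (x >= x1 - side)
    near_y = (y <= y0 + side) | (y >= y1 - side)
    return float(np.mean(near_x & near_y))
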