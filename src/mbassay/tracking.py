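"""Single-animal tracking by background subtraction and image moments.

Recovers a per-frame body ellipse (centroid, axis lengths, orientation) for a
dark mouse on light bedding from a top-down frame stack.  The pipeline is
median background -> absolute difference -> threshold (Otsu by default) ->
largest connected component -> second-order moments.

Image coordinates are pixel-centered and 0-based, origin top-left, x
rightward (columns), y downward (rows).  Orientation ``theta_rad`` is the
angle of the body major axis measured from the +x axis, reduced to [0, pi)
(a body axis has no head/tail polarity here).  Conversion to centimeters
happens downstream, in the activity module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

TRACK_COLUMNS = [
    "frame",
    "t_s",
    "x_px",
    "y_px",
    "major_px",
    "minor_px",
    "theta_rad",
    "valid",
]


@dataclass
class ArenaGeometry:
    """Arena corner pixel coordinates plus physical dimensions.

    ``corner_px`` is a (4, 2) array of (x, y) image points ordered TL, TR,
    BR, BL.  Defaults follow a 26.6 x 42.5 cm test cage filmed at
    10 px/cm.
    """

    corner_px: np.ndarray
    width_cm: float = 26.6
    height_cm: float = 42.5
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        self.corner_px = np.asarray(self.corner_px, dtype=float)
        if self.corner_px.shape != (4, 2):
            raise ValueError("corner_px must be four (x, y) points")

    @classmethod
    def from_rect(
        cls, width_px: float, height_px: float, width_cm: float = 26.6, height_cm: float = 42.5
    ) -> "ArenaGeometry":
        corners = np.array(
            [[0, 0], [width_px, 0], [width_px, height_px], [0, height_px]], dtype=float
        )
        return cls(corner_px=corners, width_cm=width_cm, height_cm=height_cm)

    def to_dict(self) -> dict:
        return {
            "corner_px": self.corner_px.tolist(),
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "px_per_cm": self.px_per_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            corner_px=np.asarray(d["corner_px"], dtype=float),
            width_cm=float(d["width_cm"]),
            height_cm=float(d["height_cm"]),
            px_per_cm=d.get("px_per_cm"),
        )


def calibrate(arena: ArenaGeometry) -> float:
    """Pixel-per-centimeter scale from arena corner points.

    Averages the top-edge estimate (TL-TR length / width_cm) and left-edge
    estimate (TL-BL length / height_cm); warns if the two disagree by more
    than 5% (skewed or mis-clicked corners).
    """
    tl, tr, br, bl = arena.corner_px
    top_len = float(np.hypot(*(tr - tl)))
    left_len = float(np.hypot(*(bl - tl)))
    if top_len <= 0 or left_len <= 0:
        raise ValueError("degenerate arena corners")
    est_w = top_len / arena.width_cm
    est_h = left_len / arena.height_cm
    if abs(est_w - est_h) / max(est_w, est_h) > 0.05:
        warnings.warn(
            f"px/cm estimates disagree: top edge {est_w:.3f}, left edge {est_h:.3f}",
            stacklevel=2,
        )
    px_per_cm = 0.5 * (est_w + est_h)
    arena.px_per_cm = px_per_cm
    return px_per_cm


def estimate_background(frames: np.ndarray, sample_stride: int = 1) -> np.ndarray:
    """Per-pixel median over every ``sample_stride``-th frame.

    With the animal at any given pixel less than half the time, the median is
    pure background.
    """
    frames = np.asarray(frames)
    sampled = frames[::sample_stride]
    if len(sampled) < 10:
        raise ValueError(f"need >= 10 sampled frames, got {len(sampled)}")
    return np.median(sampled.astype(float), axis=0)


def _ellipse_from_moments(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    """Centroid + ellipse parameters of a binary blob via image moments.

    Returns (x, y, major, minor, theta).  Axis lengths follow the standard
    uniform-ellipse convention: full length = 4 * sqrt(eigenvalue of the
    pixel covariance matrix).
    """
    ys, xs = np.nonzero(mask)
    n = len(xs)
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = ys - cy
    var_x = float(dx @ dx) / n
    var_y = float(dy @ dy) / n
    cov = float(dx @ dy) / n
    theta = 0.5 * np.arctan2(2.0 * cov, var_x - var_y) % np.pi
    common = np.sqrt(max((var_x - var_y) ** 2 + 4 * cov**2, 0.0))
    lam1 = 0.5 * (var_x + var_y + common)
    lam2 = 0.5 * (var_x + var_y - common)
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    return float(cx), float(cy), float(major), float(minor), float(theta)


def empty_track(n_frames: int, fps: float) -> pd.DataFrame:
    frames = np.arange(n_frames, dtype=int)
    return pd.DataFrame(
        {
            "frame": frames,
            "t_s": frames / fps,
            "x_px": np.nan,
            "y_px": np.nan,
            "major_px": np.nan,
            "minor_px": np.nan,
            "theta_rad": np.nan,
            "valid": False,
        }
    )


def track_frames(
    frames: np.ndarray,
    background: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 20,
    fps: float = 25.0,
) -> pd.DataFrame:
    """Track the animal in every frame of a grayscale stack.

    Parameters
    ----------
    frames : (n, h, w) array
        Grayscale frame stack.
    background : (h, w) array
        Animal-free background (see :func:`estimate_background`).
    threshold : float, optional
        Fixed threshold on the absolute difference image; ``None`` selects
        Otsu's threshold per frame.
    min_area_px : int
        Minimum connected-component area to accept as the animal; frames
        with no qualifying component are marked invalid.

    Returns
    -------
    DataFrame with the :data:`TRACK_COLUMNS` schema, one row per frame.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (n, h, w) frame stack")
    if frames.shape[0] == 0:
        raise ValueError("empty frame stack")
    if frames.shape[1:] != np.asarray(background).shape:
        raise ValueError("frames and background shapes differ")
    background = np.asarray(background, dtype=float)

    track = empty_track(frames.shape[0], fps)
    xs = np.full(len(track), np.nan)
    ys = np.full(len(track), np.nan)
    majors = np.full(len(track), np.nan)
    minors = np.full(len(track), np.nan)
    thetas = np.full(len(track), np.nan)
    valid = np.zeros(len(track), dtype=bool)

    for i, frame in enumerate(frames):
        diff = np.abs(frame.astype(float) - background)
        if threshold is None:
            if diff.max() - diff.min() < 1e-9:
                continue  # featureless difference image, e.g. blank frame
            thr = threshold_otsu(diff)
        else:
            thr = threshold
        mask = diff > thr
        labeled, n_comp = ndimage.label(mask)
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))
        best = int(np.argmax(sizes)) + 1  # argmax keeps first on ties -> scan order
        if sizes[best - 1] < min_area_px:
            continue
        cx, cy, major, minor, theta = _ellipse_from_moments(labeled == best)
        xs[i], ys[i] = cx, cy
        majors[i], minors[i], thetas[i] = major, minor, theta
        valid[i] = True

    track["x_px"] = xs
    track["y_px"] = ys
    track["major_px"] = majors
    track["minor_px"] = minors
    track["theta_rad"] = thetas
    track["valid"] = valid
    return track


def interpolate_gaps(track: pd.DataFrame, max_gap_frames: int = 5) -> pd.DataFrame:
    """Fill short tracking dropouts by linear interpolation.

    Invalid runs of length <= ``max_gap_frames`` bounded by valid frames on
    both sides are interpolated (orientation via its doubled-angle vector, to
    respect the pi-periodicity) and marked valid; longer runs, and runs
    touching either end of the session, are left untouched.
    """
    out = track.copy()
    valid = out["valid"].to_numpy(bool)
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run_len = j - i
        if i > 0 and j < n and run_len <= max_gap_frames:
            lo, hi = i - 1, j
            for col in ("x_px", "y_px", "major_px", "minor_px"):
                a, b = out.at[lo, col], out.at[hi, col]
                w = (np.arange(i, j) - lo) / (hi - lo)
                out.loc[i : j - 1, col] = a + w * (b - a)
            ta, tb = out.at[lo, "theta_rad"], out.at[hi, "theta_rad"]
            w = (np.arange(i, j) - lo) / (hi - lo)
            sin2 = (1 - w) * np.sin(2 * ta) + w * np.sin(2 * tb)
            cos2 = (1 - w) * np.cos(2 * ta) + w * np.cos(2 * tb)
            out.loc[i : j - 1, "theta_rad"] = (np.arctan2(sin2, cos2) / 2.0) % np.pi
            out.loc[i : j - 1, "valid"] = True
        i = j
    return out
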