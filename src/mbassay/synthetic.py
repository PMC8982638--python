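"""Synthetic marble-burying sessions with known ground truth.

Every downstream stage (tracking, classification, bout statistics, coverage
scoring, agreement) is tested against data from this module, which emulates:

* confined random-walk trajectories with corner-biased dwell and embedded
  low-speed burying epochs (Ornstein-Uhlenbeck velocity, reflecting walls);
* rendered grayscale frame stacks — a dark body ellipse over textured bright
  bedding plus optional Gaussian pixel noise;
* end-of-test marble photographs: blue disks on bedding, each occluded by a
  bedding-colored circular-segment mask of a requested area fraction;
* noisy observer label series (independent per-frame flips);
* Gaussian two-class feature tables with a known informative axis.

All generators are pure functions of their spec and seed.  Defaults mirror a
standard 30-min session: 26.6 x 42.5 cm arena filmed top-down at 25 fps with
20 marbles in four rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .bouts import Bout, BoutSet
from .labels import LabelSeries

ANIMAL_INTENSITY = 60.0
BEDDING_INTENSITY = 200.0
BEDDING_RGB = (186, 158, 118)
MARBLE_RGB = (45, 65, 185)


@dataclass
class SessionSpec:
    """Parameters of one simulated session.

    Arena size and frame rate default to the standard test cage (26.6 x
    42.5 cm, 25 fps); ``px_per_cm`` fixes the rendering scale.  Burying bouts
    are low-speed epochs whose durations are drawn from a truncated normal
    and whose anchor point is a corner with probability ``corner_bias``.
    """

    duration_s: float = 1800.0
    fps: float = 25.0
    arena_w_cm: float = 26.6
    arena_h_cm: float = 42.5
    n_bouts: int = 20
    bout_duration_s_mean: float = 8.0
    bout_duration_s_sd: float = 4.0
    corner_bias: float = 0.8
    speed_cm_s_mean: float = 6.0
    px_per_cm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be non-negative")
        if not 0.0 <= self.corner_bias <= 1.0:
            raise ValueError("corner_bias must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def arena_w_px(self) -> float:
        return self.arena_w_cm * self.px_per_cm

    @property
    def arena_h_px(self) -> float:
        return self.arena_h_cm * self.px_per_cm


@dataclass
class GroundTruth:
    """Everything a parameter-recovery test needs to know."""

    track: pd.DataFrame | None = None
    labels: LabelSeries | None = None
    bouts: BoutSet | None = None
    per_marble_coverage: list[float] = field(default_factory=list)
    per_marble_visible_px: list[int] = field(default_factory=list)
    per_marble_full_px: list[int] = field(default_factory=list)
    marble_centers_px: list[tuple[float, float]] = field(default_factory=list)
    marble_radius_px: float = 0.0


def _schedule_bouts(spec: SessionSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping bout frame intervals separated by >= 1 s of rest."""
    if spec.n_bouts == 0:
        return []
    durs_s = np.empty(spec.n_bouts)
    for i in range(spec.n_bouts):
        d = -1.0
        while d <= 0:
            d = rng.normal(spec.bout_duration_s_mean, spec.bout_duration_s_sd)
        durs_s[i] = d
    dur_frames = np.maximum(np.round(durs_s * spec.fps).astype(int), 1)
    n = spec.n_frames
    gap_min = int(np.ceil(spec.fps))  # >= 1 s between bouts and at both ends
    slack = n - dur_frames.sum() - (spec.n_bouts + 1) * gap_min
    if slack < 0:
        raise ValueError("requested bouts do not fit in the session")
    extra = np.floor(rng.dirichlet(np.ones(spec.n_bouts + 1)) * slack).astype(int)
    intervals = []
    cursor = gap_min + extra[0]
    for i, d in enumerate(dur_frames):
        intervals.append((cursor, cursor + int(d)))
        cursor += int(d) + gap_min + extra[i + 1]
    return intervals


def _corner_centers(spec: SessionSpec) -> np.ndarray:
    side = min(spec.arena_w_px, spec.arena_h_px) / 4.0
    w, h = spec.arena_w_px, spec.arena_h_px
    half = side / 2.0
    return np.array(
        [[half, half], [w - half, half], [w - half, h - half], [half, h - half]]
    )


def make_trajectory(spec: SessionSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a confined random walk with embedded burying epochs.

    Velocity follows an Ornstein-Uhlenbeck process with reflecting walls.
    During a burying bout the speed is capped at 20% of the session mean and
    the animal is attracted toward the bout anchor (a corner-zone center
    with probability ``corner_bias``, otherwise a random interior point).

    Returns the per-frame track (pixels) and the ground truth (labels and
    bouts exactly matching the scheduled epochs).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    dt = 1.0 / spec.fps
    w, h = spec.arena_w_px, spec.arena_h_px

    body_major = 6.0 * spec.px_per_cm  # ~6 cm mouse body
    body_minor = body_major / 2.0
    margin = body_major / 2.0 + 1.0
    if 2 * margin >= min(w, h):
        raise ValueError("body ellipse does not fit in the arena")

    intervals = _schedule_bouts(spec, rng)
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True

    corners = _corner_centers(spec)
    anchors = []
    for _ in intervals:
        if rng.random() < spec.corner_bias:
            anchors.append(corners[rng.integers(4)])
        else:
            anchors.append(
                np.array(
                    [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
                )
            )
    anchor_of_frame = np.full(n, -1, dtype=int)
    for k, (s, e) in enumerate(intervals):
        anchor_of_frame[s:e] = k
    # pre-bout approach: the animal walks to the bout site during the
    # preceding rest gap (up to 5 s), at normal speed, labeled non-burying
    approach_of_frame = np.full(n, -1, dtype=int)
    approach_frames = int(round(5.0 * spec.fps))
    prev_end = 0
    for k, (s, e) in enumerate(intervals):
        a0 = max(prev_end, s - approach_frames)
        approach_of_frame[a0:s] = k
        prev_end = e

    speed_px = spec.speed_cm_s_mean * spec.px_per_cm
    tau = 0.5  # velocity relaxation time, seconds
    sigma_v = speed_px / np.sqrt(np.pi / 2.0)  # per-axis SD giving that mean speed
    sigma = sigma_v * np.sqrt(2.0 / tau)
    bout_cap = 0.2 * speed_px

    pos = np.empty((n, 2))
    theta = np.empty(n)
    p = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
    v = rng.normal(0.0, sigma_v, 2)
    prev_theta = rng.uniform(0, np.pi)
    noise = rng.normal(0.0, 1.0, (n, 2))
    for i in range(n):
        v = v + (-v / tau) * dt + sigma * np.sqrt(dt) * noise[i]
        if mask[i]:
            v = v + 3.0 * (anchors[anchor_of_frame[i]] - p) * dt
            speed = np.hypot(*v)
            if speed > bout_cap:
                v = v * (bout_cap / speed)
        elif approach_of_frame[i] >= 0:
            # steer toward the upcoming bout anchor at normal travel speed
            target = anchors[approach_of_frame[i]] - p
            dist = np.hypot(*target)
            if dist > 1.0:
                v = 0.6 * v + 0.4 * speed_px * 1.5 * target / dist
        p = p + v * dt
        # reflecting walls, keeping the body ellipse inside the arena
        for ax, lim in ((0, w), (1, h)):
            if p[ax] < margin:
                p[ax] = 2 * margin - p[ax]
                v[ax] = -v[ax]
            elif p[ax] > lim - margin:
                p[ax] = 2 * (lim - margin) - p[ax]
                v[ax] = -v[ax]
            p[ax] = np.clip(p[ax], margin, lim - margin)
        pos[i] = p
        if np.hypot(*v) > 1e-6:
            prev_theta = np.arctan2(v[1], v[0]) % np.pi
        theta[i] = prev_theta

    frames = np.arange(n, dtype=int)
    track = pd.DataFrame(
        {
            "frame": frames,
            "t_s": frames / spec.fps,
            "x_px": pos[:, 0],
            "y_px": pos[:, 1],
            "major_px": body_major,
            "minor_px": body_minor,
            "theta_rad": theta,
            "valid": True,
        }
    )
    bouts = BoutSet(
        bouts=[Bout(s, e, (e - s) / spec.fps) for s, e in intervals],
        fps=spec.fps,
        n_frames=n,
    )
    truth = GroundTruth(track=track, labels=LabelSeries.from_mask(mask), bouts=bouts)
    return track, truth


def _ellipse_mask(
    shape: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float
) -> tuple[slice, slice, np.ndarray]:
    """Boolean mask of a filled rotated ellipse, restricted to its bbox."""
    h, w = shape
    r0 = max(int(np.floor(cy - a)), 0)
    r1 = min(int(np.ceil(cy + a)) + 1, h)
    c0 = max(int(np.floor(cx - a)), 0)
    c1 = min(int(np.ceil(cx + a)) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    t = -dx * np.sin(theta) + dy * np.cos(theta)
    return slice(r0, r1), slice(c0, c1), (u / a) ** 2 + (t / b) ** 2 <= 1.0


def render_frames(
    track: pd.DataFrame,
    spec: SessionSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a grayscale stack: dark ellipse over textured bright bedding.

    Returns a float32 (n, h, w) array in [0, 255]; frame count equals track
    length.  Bit-identical for identical inputs and seed.
    """
    rng = np.random.default_rng(seed)
    h = int(round(spec.arena_h_px))
    w = int(round(spec.arena_w_px))
    major = track["major_px"].to_numpy(float)
    if np.nanmax(major) >= min(w, h):
        raise ValueError("body ellipse larger than the arena")
    x = track["x_px"].to_numpy(float)
    y = track["y_px"].to_numpy(float)
    if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
        raise ValueError("track leaves the rendered arena")

    texture = BEDDING_INTENSITY + 10.0 * gaussian_filter(rng.normal(0, 1, (h, w)), 4.0)
    texture = np.clip(texture, 0, 255).astype(np.float32)

    minor = track["minor_px"].to_numpy(float)
    theta = track["theta_rad"].to_numpy(float)
    n = len(track)
    stack = np.empty((n, h, w), dtype=np.float32)
    for i in range(n):
        img = texture.copy()
        rs, cs, mask = _ellipse_mask((h, w), x[i], y[i], major[i] / 2, minor[i] / 2, theta[i])
        img[rs, cs][mask] = ANIMAL_INTENSITY
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, (h, w)).astype(np.float32)
        stack[i] = np.clip(img, 0, 255)
    return stack


def _chord_offset(frac: float) -> float:
    """Signed offset d/r such that the disk area with u >= d is ``frac``.

    Area of the circular segment {u >= d} of the unit disk is
    acos(d) - d * sqrt(1 - d^2); solved for d by bisection.
    """
    if frac <= 0.0:
        return 1.0
    if frac >= 1.0:
        return -1.0

    def seg(d: float) -> float:
        return (np.arccos(d) - d * np.sqrt(1 - d * d)) / np.pi - frac

    return brentq(seg, -1.0, 1.0)


def make_marble_image(
    n_marbles: int = 20,
    coverage: list[float] | None = None,
    seed: int = 0,
    radius_px: float = 20.0,
    noise_sd: float = 4.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render an end-of-test marble photograph with known coverage.

    Blue disks are laid out in rows of five on bedding-colored background;
    each disk is occluded by a bedding-colored circular-segment mask whose
    area fraction equals the requested coverage (0 = fully visible, 1 =
    fully buried), oriented at a random angle.

    Returns the uint8 RGB image and a :class:`GroundTruth` carrying the true
    per-marble coverage, visible pixel count and full-disk pixel count.
    """
    if coverage is None:
        coverage = [0.0] * n_marbles
    if len(coverage) != n_marbles:
        raise ValueError("coverage list length must equal n_marbles")
    if any(not 0.0 <= c <= 1.0 for c in coverage):
        raise ValueError("coverage fractions must be in [0, 1]")

    rng = np.random.default_rng(seed)
    per_row = 5
    n_rows = int(np.ceil(n_marbles / per_row))
    pitch = 5.0 * radius_px
    if pitch <= 2 * radius_px:
        raise ValueError("marble layout overflow")
    w = int(per_row * pitch)
    h = int(n_rows * pitch)

    img = np.empty((h, w, 3), dtype=float)
    for ch, base in enumerate(BEDDING_RGB):
        img[..., ch] = base + rng.normal(0, noise_sd, (h, w))

    truth = GroundTruth(marble_radius_px=radius_px)
    for k in range(n_marbles):
        row, col = divmod(k, per_row)
        cx = (col + 0.5) * pitch + rng.uniform(-2, 2)
        cy = (row + 0.5) * pitch + rng.uniform(-2, 2)
        rr, cc = np.mgrid[0:h, 0:w]
        # restrict to bbox for speed
        r0, r1 = int(cy - radius_px) - 2, int(cy + radius_px) + 3
        c0, c1 = int(cx - radius_px) - 2, int(cx + radius_px) + 3
        rr = rr[r0:r1, c0:c1]
        cc = cc[r0:r1, c0:c1]
        dx = cc - cx
        dy = rr - cy
        disk = dx * dx + dy * dy <= radius_px * radius_px
        full_px = int(disk.sum())

        phi = rng.uniform(0, 2 * np.pi)
        d = _chord_offset(coverage[k]) * radius_px
        u = dx * np.cos(phi) + dy * np.sin(phi)
        visible = disk & (u < d)

        sub = img[r0:r1, c0:c1]
        for ch, base in enumerate(MARBLE_RGB):
            plane = sub[..., ch]
            plane[visible] = base + rng.normal(0, noise_sd, int(visible.sum()))
        truth.per_marble_coverage.append(float(coverage[k]))
        truth.per_marble_visible_px.append(int(visible.sum()))
        truth.per_marble_full_px.append(full_px)
        truth.marble_centers_px.append((float(cx), float(cy)))

    return np.clip(img, 0, 255).astype(np.uint8), truth


def make_observer_labels(
    truth: LabelSeries,
    miss_rate: float,
    false_alarm_rate: float,
    seed: int = 0,
) -> LabelSeries:
    """Simulate an imperfect observer re-annotating a true label series.

    Each positive frame is flipped to negative with probability
    ``miss_rate``; each negative frame to positive with
    ``false_alarm_rate``; flips are independent across frames.
    """
    if not (0.0 <= miss_rate <= 1.0 and 0.0 <= false_alarm_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = truth.mask.copy()
    u = rng.random(len(mask))
    flip = np.where(mask, u < miss_rate, u < false_alarm_rate)
    return LabelSeries.from_mask(mask ^ flip)


def make_feature_table(
    labels: LabelSeries,
    class_separation: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_features: int = 8,
) -> pd.DataFrame:
    """Per-frame Gaussian features with a known informative axis.

    Column ``f0`` carries the full class-mean shift (``class_separation``,
    positive frames higher); the remaining columns are pure noise.  With
    unit noise the single-axis Bayes accuracy is Phi(class_separation / 2).
    """
    if class_separation < 0:
        raise ValueError("class separation must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(labels)
    X = rng.normal(0.0, noise_sd, (n, n_features))
    X[:, 0] += class_separation * labels.mask
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
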