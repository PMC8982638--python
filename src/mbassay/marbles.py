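"""Marble coverage scoring from end-of-test photographs.

Marbles are segmented from the bedding by HSV color thresholding and
connected components; the visible surface area is measured per marble and
converted to a coverage fraction against a baseline (pre-test) area.  A
marble counts as buried when its coverage reaches the burial threshold —
the two literature conventions are 50% and two-thirds; the stricter
two-thirds is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from skimage.color import rgb2hsv

# Hue/saturation/value ranges (each in [0, 1]) selecting blue glass marbles
# against tan bedding; tune per setup.
DEFAULT_BLUE_HSV = {"h": (0.50, 0.75), "s": (0.25, 1.0), "v": (0.15, 1.0)}

DEFAULT_BURIAL_THRESHOLD = 2.0 / 3.0


@dataclass
class MarbleRecord:
    id: int
    visible_area_px2: float
    baseline_area_px2: float
    coverage_fraction: float
    buried: bool


@dataclass
class MarbleReport:
    marbles: list[MarbleRecord] = field(default_factory=list)
    n_marbles_detected: int = 0
    n_buried: int = 0
    total_uncovered_area_px2: float = 0.0
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD
    expected_count_mismatch: bool = False

    def coverages(self) -> np.ndarray:
        return np.array([m.coverage_fraction for m in self.marbles], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.marbles],
                "visible_area_px2": [m.visible_area_px2 for m in self.marbles],
                "baseline_area_px2": [m.baseline_area_px2 for m in self.marbles],
                "coverage_fraction": [m.coverage_fraction for m in self.marbles],
                "buried": [m.buried for m in self.marbles],
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_marbles_detected": self.n_marbles_detected,
            "n_buried": self.n_buried,
            "total_uncovered_area_px2": self.total_uncovered_area_px2,
            "burial_threshold": self.burial_threshold,
            "expected_count_mismatch": self.expected_count_mismatch,
            "marbles": self.to_frame().to_dict(orient="records"),
        }


def segment_marbles(
    image: np.ndarray,
    color_range: dict | None = None,
    min_area_px: int = 30,
    max_area_px: int = 100_000,
) -> list[np.ndarray]:
    """Segment marbles by HSV color thresholding and connected components.

    Returns one boolean mask per accepted component, sorted row-major by
    centroid (top row first, then left to right) so ids are stable across
    before/after photographs of the same layout.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB color image")
    rng = color_range or DEFAULT_BLUE_HSV
    hsv = rgb2hsv(image)
    mask = np.ones(hsv.shape[:2], dtype=bool)
    for ch, key in enumerate(("h", "s", "v")):
        lo, hi = rng[key]
        mask &= (hsv[..., ch] >= lo) & (hsv[..., ch] <= hi)
    labeled, n_comp = ndimage.label(mask)
    if n_comp == 0:
        warnings.warn("no marble-colored components found", stacklevel=2)
        return []
    masks = []
    for i in range(1, n_comp + 1):
        comp = labeled == i
        area = int(comp.sum())
        if min_area_px <= area <= max_area_px:
            masks.append(comp)
    if not masks:
        warnings.warn("no components within the area bounds", stacklevel=2)
        return []
    # row-major sort; rows found by gap clustering of centroid rows, since a
    # mostly-covered marble's visible sliver can shift its centroid by a radius
    cents = np.array([ndimage.center_of_mass(m) for m in masks])  # (row, col)
    gap = max(float(np.max([np.ptp(np.nonzero(m)[0]) + 1 for m in masks])), 1.0)
    by_row = np.argsort(cents[:, 0])
    row_bucket = np.empty(len(masks), dtype=int)
    bucket = 0
    prev = cents[by_row[0], 0]
    for i in by_row:
        if cents[i, 0] - prev > gap:
            bucket += 1
        row_bucket[i] = bucket
        prev = cents[i, 0]
    order = np.lexsort((cents[:, 1], row_bucket))
    return [masks[i] for i in order]


def measure_coverage(
    masks: list[np.ndarray],
    baseline_area_px2: float | np.ndarray | None = None,
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    expected_count: int | None = None,
) -> MarbleReport:
    """Per-marble coverage fractions and burial calls from visible masks.

    ``baseline_area_px2`` is the full (uncovered) marble area — from a
    pre-test image, the known disk area, or per-marble values; when omitted
    it falls back to the median detected area, which is only sound if most
    marbles are uncovered.  When ``expected_count`` exceeds the number of
    detected components, the missing marbles are fully buried and enter the
    report with coverage 1.
    """
    areas = np.array([float(m.sum()) for m in masks])
    n_det = len(areas)
    if baseline_area_px2 is None:
        if n_det == 0:
            raise ValueError("cannot infer baseline area from zero components")
        baseline = np.full(max(n_det, expected_count or 0), float(np.median(areas)))
    else:
        baseline = np.asarray(baseline_area_px2, dtype=float)
        if baseline.ndim == 0:
            baseline = np.full(max(n_det, expected_count or 0), float(baseline))
    if np.any(baseline <= 0):
        raise ValueError("baseline area must be positive")

    mismatch = False
    n_total = n_det
    if expected_count is not None and expected_count != n_det:
        mismatch = True
        n_total = max(expected_count, n_det)

    records = []
    for i in range(n_total):
        visible = areas[i] if i < n_det else 0.0
        base = baseline[i] if i < len(baseline) else float(baseline[-1])
        cov = float(np.clip(1.0 - visible / base, 0.0, 1.0))
        records.append(
            MarbleRecord(
                id=i,
                visible_area_px2=visible,
                baseline_area_px2=base,
                coverage_fraction=cov,
                buried=cov >= burial_threshold,
            )
        )
    return MarbleReport(
        marbles=records,
        n_marbles_detected=n_det,
        n_buried=sum(r.buried for r in records),
        total_uncovered_area_px2=float(areas.sum()),
        burial_threshold=burial_threshold,
        expected_count_mismatch=mismatch,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    target = abs(rho)
    for perm in permutations(range(n)):
        r = sps.spearmanr(rx, ry[list(perm)]).statistic
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_scorings(
    values_a: np.ndarray,
    values_b: np.ndarray,
    exact_max_n: int = 8,
) -> tuple[pd.DataFrame, float, float]:
    """Rank correlation between two per-animal scoring methods.

    Returns the paired table, Spearman's rho, and a two-sided p-value — an
    exact permutation p (all n! rank orderings) when n <= ``exact_max_n``,
    the asymptotic p otherwise.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired scorings must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    table = pd.DataFrame({"method_a": x, "method_b": y})
    return table, rho, p
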