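"""Frame-level burying classification with window features and boosting.

The representation follows the JAABA recipe: per-frame kinematic features
(speed, acceleration, turn rate, body-ellipse shape, wall/corner distances,
local pixel change) are expanded into sliding-window statistics (mean, std,
min, max, end-minus-start at several radii) and fed to a boosted ensemble of
shallow trees.  Cross-validation folds are stratified by contiguous
same-label segments rather than shuffled frames, because adjacent frames are
near-duplicates and frame-level shuffling leaks temporal information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .labels import POSITIVE, UNANNOTATED, LabelSeries
from .tracking import ArenaGeometry

MODEL_SCHEMA_VERSION = 1

BASE_FEATURES = [
    "speed_px_s",
    "accel_px_s2",
    "turn_rate_rad_s",
    "ellipse_area_px2",
    "ellipse_aspect",
    "dist_to_nearest_wall_px",
    "dist_to_nearest_corner_px",
    "local_pixel_change",
]

DEFAULT_WINDOW_RADII = (2, 6, 12)
DEFAULT_WINDOW_STATS = ("mean", "std", "min", "max", "end_minus_start")


def compute_frame_features(
    track: pd.DataFrame,
    arena: ArenaGeometry,
    frames: np.ndarray | None = None,
    patch_radius_px: int = 30,
) -> pd.DataFrame:
    """Per-frame kinematic and positional features from a track.

    Kinematics use central differences (one-sided at the series ends); wall
    and corner distances come from the arena's bounding rectangle.
    ``local_pixel_change`` — the mean absolute frame-to-frame intensity
    change in a disk around the centroid — is only computed when the raw
    ``frames`` stack is supplied; otherwise the column is all-NaN (absent).
    Invalid track frames yield NaN rows.
    """
    valid = track["valid"].to_numpy(bool)
    if not valid.any():
        raise ValueError("track has no valid frames")
    n = len(track)
    fps = 1.0 / np.diff(track["t_s"].to_numpy())[0] if n > 1 else 25.0
    x = np.where(valid, track["x_px"].to_numpy(float), np.nan)
    y = np.where(valid, track["y_px"].to_numpy(float), np.nan)

    vx = np.gradient(x) * fps
    vy = np.gradient(y) * fps
    speed = np.hypot(vx, vy)
    accel = np.hypot(np.gradient(vx), np.gradient(vy)) * fps
    with np.errstate(invalid="ignore"):
        heading = np.arctan2(vy, vx)
    heading_u = np.unwrap(np.where(np.isnan(heading), 0.0, heading))
    turn_rate = np.gradient(heading_u) * fps
    turn_rate = np.where(np.isnan(heading), np.nan, turn_rate)

    major = track["major_px"].to_numpy(float)
    minor = track["minor_px"].to_numpy(float)
    area = np.pi * (major / 2.0) * (minor / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = major / minor

    xs, ys = arena.corner_px[:, 0], arena.corner_px[:, 1]
    x0, x1, y0, y1 = xs.min(), xs.max(), ys.min(), ys.max()
    wall = np.minimum.reduce([x - x0, x1 - x, y - y0, y1 - y])
    corner = np.min(
        [np.hypot(x - cx, y - cy) for cx, cy in arena.corner_px], axis=0
    )

    pix = np.full(n, np.nan)
    if frames is not None:
        frames = np.asarray(frames, dtype=float)
        h, w = frames.shape[1:]
        rr, cc = np.mgrid[0:h, 0:w]
        for i in range(1, n):
            if not (valid[i] and valid[i - 1]):
                continue
            r0 = max(int(y[i]) - patch_radius_px, 0)
            r1 = min(int(y[i]) + patch_radius_px + 1, h)
            c0 = max(int(x[i]) - patch_radius_px, 0)
            c1 = min(int(x[i]) + patch_radius_px + 1, w)
            dr = rr[r0:r1, c0:c1] - y[i]
            dc = cc[r0:r1, c0:c1] - x[i]
            disk = dr * dr + dc * dc <= patch_radius_px**2
            diff = np.abs(frames[i, r0:r1, c0:c1] - frames[i - 1, r0:r1, c0:c1])
            pix[i] = diff[disk].mean()
        if n > 1 and valid[0] and valid[1]:
            pix[0] = pix[1]

    feats = pd.DataFrame(
        {
            "speed_px_s": speed,
            "accel_px_s2": accel,
            "turn_rate_rad_s": turn_rate,
            "ellipse_area_px2": np.where(valid, area, np.nan),
            "ellipse_aspect": np.where(valid, aspect, np.nan),
            "dist_to_nearest_wall_px": wall,
            "dist_to_nearest_corner_px": corner,
            "local_pixel_change": pix,
        }
    )
    return feats


def _end_minus_start(values: np.ndarray, radius: int) -> np.ndarray:
    n = len(values)
    idx = np.arange(n)
    hi = np.minimum(idx + radius, n - 1)
    lo = np.maximum(idx - radius, 0)
    return values[hi] - values[lo]


def windowize(
    features: pd.DataFrame,
    window_radii_frames: tuple[int, ...] = DEFAULT_WINDOW_RADII,
    stats: tuple[str, ...] = DEFAULT_WINDOW_STATS,
) -> pd.DataFrame:
    """Expand per-frame features into centered sliding-window statistics.

    For each base feature, radius r and statistic, a column named
    ``{feature}_r{r}_{stat}`` is computed over the window [i-r, i+r],
    truncated at the series edges.  ``std`` is the population standard
    deviation (ddof 0); NaN frames inside a window are ignored.
    """
    if any(r < 1 for r in window_radii_frames):
        raise ValueError("window radii must be >= 1")
    cols = {}
    for name in features.columns:
        s = features[name]
        vals = s.to_numpy(float)
        for r in window_radii_frames:
            roll = s.rolling(2 * r + 1, center=True, min_periods=1)
            for stat in stats:
                key = f"{name}_r{r}_{stat}"
                if stat == "mean":
                    cols[key] = roll.mean().to_numpy()
                elif stat == "std":
                    cols[key] = roll.std(ddof=0).to_numpy()
                elif stat == "min":
                    cols[key] = roll.min().to_numpy()
                elif stat == "max":
                    cols[key] = roll.max().to_numpy()
                elif stat == "end_minus_start":
                    cols[key] = _end_minus_start(vals, r)
                else:
                    raise ValueError(f"unknown window statistic: {stat}")
    return pd.DataFrame(cols, index=features.index)


@dataclass
class BuryingClassifier:
    """Boosted shallow-tree frame classifier plus its feature contract."""

    estimator: HistGradientBoostingClassifier
    feature_names: list[str]
    schema_version: int = MODEL_SCHEMA_VERSION

    def decision_scores(self, window_features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in window_features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing[:3]}...")
        X = window_features[self.feature_names].to_numpy(float)
        return self.estimator.decision_function(X)

    def save(self, path) -> None:
        joblib.dump(
            {
                "schema_version": self.schema_version,
                "feature_names": self.feature_names,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "BuryingClassifier":
        d = joblib.load(path)
        return cls(
            estimator=d["estimator"],
            feature_names=list(d["feature_names"]),
            schema_version=int(d["schema_version"]),
        )


def train_classifier(
    window_features: pd.DataFrame,
    labels: LabelSeries,
    n_rounds: int = 100,
    max_depth: int = 2,
    seed: int = 0,
) -> BuryingClassifier:
    """Train the boosted ensemble on the annotated frames only.

    Unannotated frames are excluded (training sets are typically balanced by
    annotating selectively, not exhaustively).  Deterministic under a fixed
    seed.
    """
    if len(window_features) != len(labels):
        raise ValueError("features and labels lengths differ")
    ann = labels.annotated
    y = labels.label[ann]
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes among annotated frames")
    X = window_features.loc[ann].to_numpy(float)
    est = HistGradientBoostingClassifier(
        max_iter=n_rounds,
        max_depth=max_depth,
        random_state=seed,
        early_stopping=False,
        class_weight="balanced",
    )
    est.fit(X, y)
    return BuryingClassifier(estimator=est, feature_names=list(window_features.columns))


def _binary_median_smooth(labels: np.ndarray, radius: int) -> np.ndarray:
    """Sliding binary median with edge truncation; ties keep the raw label."""
    if radius <= 0:
        return labels.copy()
    n = len(labels)
    csum = np.concatenate(([0], np.cumsum(labels.astype(int))))
    idx = np.arange(n)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, n - 1) + 1
    pos = csum[hi] - csum[lo]
    size = hi - lo
    out = labels.copy()
    out[2 * pos > size] = True
    out[2 * pos < size] = False
    return out


def predict_frames(
    model: BuryingClassifier,
    window_features: pd.DataFrame,
    threshold: float = 0.0,
    smooth_radius_frames: int = 2,
) -> LabelSeries:
    """Score every frame and emit smoothed binary labels.

    The score is the ensemble margin; the threshold is applied to the raw
    score, after which the binary labels (not the scores) are median-smoothed
    with the given radius.
    """
    scores = model.decision_scores(window_features)
    raw = scores >= threshold
    smoothed = _binary_median_smooth(raw, smooth_radius_frames)
    return LabelSeries(label=smoothed.astype(np.int8), score=scores)


@dataclass
class CVReport:
    """Per-class cross-validated accuracies and the confusion counts."""

    acc_burying: float
    acc_nonburying: float
    n_frames_annotated: int
    fold_assignment: str
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def to_dict(self) -> dict:
        return {
            "acc_burying": self.acc_burying,
            "acc_nonburying": self.acc_nonburying,
            "n_frames_annotated": self.n_frames_annotated,
            "fold_assignment": self.fold_assignment,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


def _label_segments(labels: LabelSeries) -> list[tuple[int, int, int]]:
    """Maximal runs of annotated frames sharing one label: (start, end, label)."""
    lab = labels.label
    segs = []
    i = 0
    n = len(lab)
    while i < n:
        if lab[i] == UNANNOTATED:
            i += 1
            continue
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        segs.append((i, j, int(lab[i])))
        i = j
    return segs


def cross_validate(
    window_features: pd.DataFrame,
    labels: LabelSeries,
    k: int = 5,
    seed: int = 0,
    n_rounds: int = 100,
    max_depth: int = 2,
) -> CVReport:
    """Segment-wise k-fold cross-validation with per-class accuracy.

    Folds are contiguous blocks of same-label segments with approximately
    equal annotated-frame counts, never shuffled frames: adjacent frames are
    near-duplicates, so any interleaved split leaks temporal information
    across the train/test boundary (and, at segment run boundaries, leaks
    the *opposite* label, biasing chance-level estimates below 0.5).  A fold
    whose training side has a single class is skipped with a warning.
    Reports acc_burying = TP/(TP+FN) and acc_nonburying = TN/(TN+FP) pooled
    over folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    segs = _label_segments(labels)
    if not segs:
        raise ValueError("no annotated frames")
    total = sum(e - s for s, e, _ in segs)
    fold_of_seg = {}
    cum = 0
    fold = 0
    fold_frames = 0
    for i, (s, e, _) in enumerate(segs):
        # advance to the next fold once this one holds its share of frames —
        # or once the remaining folds would otherwise starve — but never
        # leave a fold empty and never run past fold k-1
        remaining = len(segs) - i
        must_advance = remaining <= (k - 1 - fold)
        if fold_frames > 0 and fold < k - 1 and (
            cum >= (fold + 1) * total / k or must_advance
        ):
            fold += 1
            fold_frames = 0
        fold_of_seg[i] = fold
        cum += e - s
        fold_frames += e - s

    tp = fn = tn = fp = 0
    for fold in range(k):
        test_frames = []
        train_frames = []
        for i, (s, e, _) in enumerate(segs):
            (test_frames if fold_of_seg[i] == fold else train_frames).extend(range(s, e))
        if not test_frames or not train_frames:
            warnings.warn(f"fold {fold} empty; skipped", stacklevel=2)
            continue
        y_train = labels.label[train_frames]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {fold} has single-class training data; skipped", stacklevel=2)
            continue
        sub = LabelSeries(label=np.where(np.isin(np.arange(len(labels)), train_frames), labels.label, UNANNOTATED))
        model = train_classifier(window_features, sub, n_rounds=n_rounds, max_depth=max_depth, seed=seed)
        scores = model.decision_scores(window_features.iloc[test_frames])
        pred = scores >= 0
        truth = labels.label[test_frames] == POSITIVE
        tp += int(np.sum(pred & truth))
        fn += int(np.sum(~pred & truth))
        tn += int(np.sum(~pred & ~truth))
        fp += int(np.sum(pred & ~truth))

    n_ann = int(labels.annotated.sum())
    acc_b = tp / (tp + fn) if tp + fn else np.nan
    acc_nb = tn / (tn + fp) if tn + fp else np.nan
    return CVReport(
        acc_burying=acc_b,
        acc_nonburying=acc_nb,
        n_frames_annotated=n_ann,
        fold_assignment=f"{k}-fold, contiguous segment blocks, seed {seed}",
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )
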