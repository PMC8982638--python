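"""Session-level orchestration: track -> features -> predict -> bouts ->
activity -> heatmap -> report, for one session or a batch.

Every stage is isolated: a failure is recorded with its stage name and the
downstream stages are skipped, so one corrupt video never aborts a batch.
Outputs are deterministic given the config, the model and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mbio
from .activity import compute_activity, corner_preference, occupancy_heatmap
from .bouts import cumulative_curve, segment_bouts, summarize_bouts
from .classify import BuryingClassifier, compute_frame_features, predict_frames, windowize
from .labels import LabelSeries
from .marbles import (
    DEFAULT_BURIAL_THRESHOLD,
    measure_coverage,
    segment_marbles,
)
from .tracking import ArenaGeometry, calibrate, estimate_background, interpolate_gaps, track_frames

log = logging.getLogger("mbassay")


@dataclass
class SessionConfig:
    """Everything one session run needs; defaults mirror the standard assay
    (25 fps, 26.6 x 42.5 cm arena, 1-s minimum bout, 20 marbles)."""

    fps: float = 25.0
    arena: ArenaGeometry | None = None  # None: rectangle from the frame size
    model_path: str | None = None
    min_bout_s: float = 1.0
    max_gap_s: float = 0.0
    heatmap_bin_px: float = 16.0
    track_threshold: float | None = None  # None: Otsu
    min_area_px: int = 20
    max_gap_frames: int = 5
    max_step_cm: float = 10.0
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD
    expected_marbles: int = 20
    smooth_radius_frames: int = 2
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["arena"] = self.arena.to_dict() if self.arena else None
        return d


def run_session(
    config: SessionConfig,
    frames: np.ndarray | str | Path | None = None,
    track: pd.DataFrame | None = None,
    labels: LabelSeries | None = None,
    marble_image: np.ndarray | None = None,
    session_id: str = "session",
) -> dict:
    """Run the full per-session pipeline and return a report bundle.

    Inputs may enter at any stage: raw ``frames`` (array or path), a
    precomputed ``track``, or precomputed ``labels`` (otherwise the model at
    ``config.model_path`` scores the frames).  The bundle maps stage names
    to results and carries an ``errors`` list of (stage, message) pairs.
    """
    bundle: dict = {"session_id": session_id, "errors": [], "config": config.to_dict()}

    if config.model_path is not None and labels is None:
        if not Path(config.model_path).exists():
            bundle["errors"].append(("config", f"model not found: {config.model_path}"))
            return bundle

    stack = None
    if frames is not None:
        try:
            stack = frames if isinstance(frames, np.ndarray) else mbio.read_frames(frames)
        except Exception as exc:
            bundle["errors"].append(("load_frames", str(exc)))
            return bundle

    if track is None:
        if stack is None:
            bundle["errors"].append(("tracking", "no frames and no track supplied"))
            return bundle
        try:
            background = estimate_background(stack, sample_stride=max(len(stack) // 50, 1))
            track = track_frames(
                stack,
                background,
                threshold=config.track_threshold,
                min_area_px=config.min_area_px,
                fps=config.fps,
            )
            track = interpolate_gaps(track, max_gap_frames=config.max_gap_frames)
        except Exception as exc:
            bundle["errors"].append(("tracking", str(exc)))
            return bundle
    bundle["track"] = track

    arena = config.arena
    if arena is None:
        if stack is not None:
            h, w = stack.shape[1:]
        else:
            w = float(np.nanmax(track["x_px"])) + 1
            h = float(np.nanmax(track["y_px"])) + 1
        arena = ArenaGeometry.from_rect(w, h)
    try:
        px_per_cm = arena.px_per_cm or calibrate(arena)
    except Exception as exc:
        bundle["errors"].append(("calibration", str(exc)))
        return bundle
    bundle["arena"] = arena

    if labels is None:
        try:
            feats = compute_frame_features(track, arena, frames=stack)
            wf = windowize(feats)
            model = BuryingClassifier.load(config.model_path)
            labels = predict_frames(model, wf, smooth_radius_frames=config.smooth_radius_frames)
        except Exception as exc:
            bundle["errors"].append(("classify", str(exc)))
            return bundle
    bundle["labels"] = labels

    try:
        bouts = segment_bouts(labels, config.fps, config.min_bout_s, config.max_gap_s)
        summary = summarize_bouts(bouts)
        curve = cumulative_curve(
            labels, config.fps, min_bout_s=config.min_bout_s, max_gap_s=config.max_gap_s
        )
        bundle["bouts"] = bouts
        bundle["bout_summary"] = summary
        bundle["cumulative_curve"] = curve
    except Exception as exc:
        bundle["errors"].append(("bouts", str(exc)))
        return bundle

    try:
        bundle["activity"] = compute_activity(track, px_per_cm, config.fps, config.max_step_cm)
        bundle["heatmaps"] = occupancy_heatmap(track, labels, arena, config.heatmap_bin_px)
        bundle["corner_preference"] = corner_preference(track, arena)
    except Exception as exc:
        bundle["errors"].append(("activity_spatial", str(exc)))
        return bundle

    if marble_image is not None:
        try:
            masks = segment_marbles(marble_image)
            bundle["marble_report"] = measure_coverage(
                masks,
                burial_threshold=config.burial_threshold,
                expected_count=config.expected_marbles,
            )
        except Exception as exc:
            bundle["errors"].append(("marblevision", str(exc)))

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _summary_dict(bundle: dict) -> dict:
    out: dict = {"session_id": bundle["session_id"]}
    if "bout_summary" in bundle:
        out.update(bundle["bout_summary"].to_dict())
    if "activity" in bundle:
        out.update(bundle["activity"].to_dict())
    if "corner_preference" in bundle:
        out["corner_preference"] = bundle["corner_preference"]
    if "marble_report" in bundle:
        rep = bundle["marble_report"]
        out["n_buried"] = rep.n_buried
        out["total_uncovered_area_px2"] = rep.total_uncovered_area_px2
    out["errors"] = [list(e) for e in bundle["errors"]]
    return out


def _write_bundle(bundle: dict, config: SessionConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = bundle["session_id"]
    if "track" in bundle:
        mbio.write_track(bundle["track"], out / f"{sid}_track.csv")
    if "labels" in bundle:
        mbio.write_labels(bundle["labels"], out / f"{sid}_labels.csv")
    if "bouts" in bundle:
        bundle["bouts"].to_frame(sid).to_csv(out / f"{sid}_bouts.csv", index=False)
    if "cumulative_curve" in bundle:
        pd.DataFrame({"cumulative_burying_s": bundle["cumulative_curve"]}).to_csv(
            out / f"{sid}_cumulative.csv", index=False
        )
    if "heatmaps" in bundle:
        mbio.write_heatmap_grid(bundle["heatmaps"].burying, out / f"{sid}_heatmap_burying.csv")
        mbio.write_heatmap_grid(
            bundle["heatmaps"].non_burying, out / f"{sid}_heatmap_nonburying.csv"
        )
    mbio.write_json(_summary_dict(bundle), out / f"{sid}_summary.json")


def run_batch(sessions: list[dict]) -> tuple[list[dict], pd.DataFrame, int]:
    """Run several sessions; one failure does not abort the rest.

    ``sessions`` items are keyword dicts for :func:`run_session` (must
    include ``config``; may include ``frames``, ``track``, ``labels``,
    ``marble_image``, ``session_id``).  Returns the bundles, a cohort
    long-format table (session_id, metric, value) ready for group
    comparison, and an exit status (nonzero if any session failed).
    """
    if not sessions:
        raise ValueError("empty batch")
    bundles = []
    rows = []
    status = 0
    for i, kw in enumerate(sessions):
        kw = dict(kw)
        kw.setdefault("session_id", f"session_{i}")
        try:
            bundle = run_session(**kw)
        except Exception as exc:  # run_session guards stages; this is belt-and-braces
            bundle = {"session_id": kw["session_id"], "errors": [("run_session", str(exc))]}
        bundles.append(bundle)
        if bundle["errors"]:
            status = 1
            log.warning("session %s failed: %s", bundle["session_id"], bundle["errors"])
        summary = _summary_dict(bundle)
        for metric, value in summary.items():
            if isinstance(value, (int, float, np.integer, np.floating)) and metric != "errors":
                rows.append(
                    {"session_id": bundle["session_id"], "metric": metric, "value": float(value)}
                )
    cohort = pd.DataFrame(rows, columns=["session_id", "metric", "value"])
    return bundles, cohort, status
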