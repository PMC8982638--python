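"""File formats: frame stacks, track/label/bout tables, configs, reports.

Tables are plain CSV, reports JSON (with a schema version), arena geometry
and session configs YAML.  Frame stacks are PNG directories or video files;
video decoding requires an imageio ffmpeg backend and fails with a clear
message when none is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .labels import LabelSeries, labels_from_events
from .tracking import TRACK_COLUMNS, ArenaGeometry

SCHEMA_VERSION = 1


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img[..., :3].mean(axis=-1)
    return img


def read_frames(path: str | Path) -> np.ndarray:
    """Load a grayscale frame stack from a PNG directory or a video file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([_to_gray(iio.imread(f).astype(np.float32)) for f in files])
    try:
        stack = iio.imread(path)
    except Exception as exc:  # no decoder for this container
        raise RuntimeError(
            f"could not decode {path}; for MP4/AVI an imageio ffmpeg backend is "
            "required — alternatively supply a directory of PNG frames"
        ) from exc
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 4:
        stack = stack[..., :3].mean(axis=-1)
    return stack


def write_frames(stack: np.ndarray, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack):
        iio.imwrite(out_dir / f"frame_{i:06d}.png", np.clip(frame, 0, 255).astype(np.uint8))


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    track[TRACK_COLUMNS].to_csv(path, index=False)


def read_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_labels(labels: LabelSeries, path: str | Path) -> None:
    labels.to_frame().to_csv(path, index=False)


def read_labels(path: str | Path) -> LabelSeries:
    return LabelSeries.from_dataframe(pd.read_csv(path))


def read_annotations(path: str | Path, n_frames: int | None = None, fps: float = 25.0) -> LabelSeries:
    """Import manual annotations: per-frame (frame, label) CSV or a
    BORIS-style event export with (behavior, start_s, stop_s) columns."""
    df = pd.read_csv(path)
    if {"start_s", "stop_s"}.issubset(df.columns):
        if n_frames is None:
            raise ValueError("n_frames is required for event-style annotations")
        return labels_from_events(df, n_frames=n_frames, fps=fps)
    if {"frame", "label"}.issubset(df.columns):
        n = n_frames if n_frames is not None else int(df["frame"].max()) + 1
        lab = np.full(n, -1, dtype=np.int8)
        named = LabelSeries.from_dataframe(df)
        lab[df["frame"].to_numpy(int)] = named.label
        return LabelSeries(label=lab)
    raise ValueError("unrecognized annotation format")


def write_json(obj: dict, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_arena(arena: ArenaGeometry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(arena.to_dict()))


def read_arena(path: str | Path) -> ArenaGeometry:
    return ArenaGeometry.from_dict(yaml.safe_load(Path(path).read_text()))


def write_heatmap_grid(grid: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(grid).to_csv(path, index=False, header=False)


def read_heatmap_grid(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy()
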