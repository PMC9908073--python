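"""Session file I/O: TIFF frame stacks, CSV ground truth, JSON manifests.

Frames travel as 8-bit grayscale multi-page TIFF; trajectories, labels,
displacements, and traces as frame-major CSV; the session manifest (seed
and every generator parameter) as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_frames(path, frames: np.ndarray) -> None:
    """Write a (F, H, W) uint8 stack as multi-page grayscale TIFF."""
    tifffile.imwrite(
        str(path), np.asarray(frames, dtype=np.uint8), photometric="minisblack"
    )


def read_frames(path) -> np.ndarray:
    """Read a grayscale frame stack (TIFF or anything imageio can decode)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        stack = iio.imread(str(path))
        if stack.ndim == 4:  # RGB video -> grayscale
            stack = stack[..., :3].mean(axis=-1)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    return stack.astype(np.uint8)


def read_label_image(path) -> np.ndarray:
    """Read a contour-mask label image (integer TIFF)."""
    return np.asarray(tifffile.imread(str(path)))


def write_trajectory(path, trajectory) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(trajectory.n_frames),
            "position_cm": trajectory.position_cm,
            "direction": trajectory.direction,
            "bin_index": trajectory.bin_index,
        }
    ).to_csv(path, index=False)


def read_labels_csv(path, column: str = "value") -> np.ndarray:
    """Per-frame label/position series from a (frame_index, value) CSV."""
    df = pd.read_csv(path)
    df = df.sort_values(df.columns[0])
    col = column if column in df.columns else df.columns[-1]
    return df[col].to_numpy()


def write_series_csv(path, name: str, values) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(values)), name: values}
    ).to_csv(path, index=False)


def write_traces(path, traces: np.ndarray) -> None:
    """Trace matrix (n_rois, n_frames) as frame-major CSV (one row per
    frame, one column per ROI)."""
    traces = np.atleast_2d(traces)
    df = pd.DataFrame(
        traces.T, columns=[f"roi_{i}" for i in range(traces.shape[0])]
    )
    df.insert(0, "frame_index", np.arange(traces.shape[1]))
    df.to_csv(path, index=False)


def read_traces(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("roi_")]
    return df[cols].to_numpy().T


def write_displacements(path, displacements) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(displacements)),
            "dx": [p.dx for p in displacements],
            "dy": [p.dy for p in displacements],
            "low_confidence": [p.low_confidence for p in displacements],
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, default=str)


def write_session(session, out_dir, manifest_extra: dict | None = None) -> Path:
    """Persist a synthetic session: frames (TIFF), trajectory/labels/true
    displacements (CSV), true traces (CSV), and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if session.frames is not None:
        write_frames(out / "frames.tif", session.frames)
    if session.trajectory is not None:
        write_trajectory(out / "trajectory.csv", session.trajectory)
    if session.behavior_labels is not None:
        write_series_csv(out / "behavior_labels.csv", "value", session.behavior_labels)
    pd.DataFrame(
        {
            "frame_index": np.arange(session.n_frames),
            "dx": session.motion.dx,
            "dy": session.motion.dy,
        }
    ).to_csv(out / "true_displacements.csv", index=False)
    write_traces(out / "true_traces.csv", session.true_traces)
    manifest = {
        "seed": session.seed,
        "n_frames": session.n_frames,
        "frame_shape": list(session.frame_shape),
        "n_cells": len(session.cells),
    }
    manifest.update(manifest_extra or {})
    write_json(out / "manifest.json", manifest)
    return out
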