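"""Stage 3 — pixel-mask ROIs, fluorescence summation, drop filtering, and
threshold spike inference.

A calcium trace is the plain sum of enhanced-image intensities over a fixed
set of pixels (no demixing — the extraction must stay causal).  Masks come
in two flavors:

* *tile* (contour-free): the 512x512 working frame is covered by a 32x32
  grid of 16x16-pixel tiles; the 124 tiles touching the frame border are
  excluded to keep stabilization edge artifacts out, leaving 900 ROIs.
* *contour*: masks ingested from an external segmentation (or from
  synthetic ground truth), each confined to a 25x25 bounding square.

Small contour masks are vulnerable to residual jitter slipping pixels in
and out of the mask; because the calcium indicator decays slowly (half
decay ~0.7 s, under 5% per 50-ms frame), any sudden large drop in a trace
is motion artifact, and the *drop filter* caps the per-frame decrease at
``delta = G * C * q``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PixelMask",
    "TraceExtractor",
    "SpikeThreshold",
    "make_tile_masks",
    "make_contour_masks",
    "extract_traces",
    "drop_filter",
    "infer_spikes",
    "per_frame_decay_fraction",
]

#: Maximum possible intensity of a single 8-bit pixel.
MAX_PIXEL_INTENSITY = 255.0

#: Drop-filter sensitivity threshold.
DEFAULT_SENSITIVITY = 0.9

#: Contour masks with at least this many pixels are left unfiltered.
SMALL_MASK_LIMIT = 50

#: Side of the square region that must contain every contour mask.
CONTOUR_REGION_SIZE = 25


@dataclass(frozen=True)
class PixelMask:
    """One ROI: a set of 0-based (row, col) pixel coordinates.

    ``kind`` is ``"tile"`` for contour-free grid tiles (always 16x16 = 256
    pixels) or ``"contour"`` for ingested neuron outlines (confined to a
    25x25 bounding region).
    """

    rows: np.ndarray
    cols: np.ndarray
    kind: str = "tile"
    label: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=np.intp))
        object.__setattr__(self, "cols", np.asarray(self.cols, dtype=np.intp))
        if self.rows.size == 0 or self.rows.size != self.cols.size:
            raise ValueError("mask must contain at least one (row, col) pair")
        if self.kind == "contour":
            span_r = self.rows.max() - self.rows.min() + 1
            span_c = self.cols.max() - self.cols.min() + 1
            if span_r > CONTOUR_REGION_SIZE or span_c > CONTOUR_REGION_SIZE:
                raise ValueError(
                    "contour mask exceeds its 25x25 bounding region"
                )

    @property
    def C(self) -> int:
        """Pixel count of the mask."""
        return int(self.rows.size)

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def make_tile_masks(frame_size: int = 512, tile: int = 16) -> list[PixelMask]:
    """Contour-free tile masks: interior tiles of a uniform square grid.

    The frame is covered by a ``(frame_size/tile)``-per-side array of square
    tiles; tiles on the outer perimeter are excluded.  With the 512/16
    defaults this yields a 32x32 grid minus its 124 border tiles = 900
    masks, emitted in raster (row-major) order, each with 256 pixels.
    """
    if frame_size % tile != 0:
        raise ValueError(f"frame_size {frame_size} not divisible by tile {tile}")
    n = frame_size // tile
    if n < 3:
        raise ValueError("grid too small to have interior tiles")
    masks = []
    rr, cc = np.mgrid[0:tile, 0:tile]
    for ti in range(1, n - 1):
        for tj in range(1, n - 1):
            masks.append(
                PixelMask(
                    rows=(rr + ti * tile).ravel(),
                    cols=(cc + tj * tile).ravel(),
                    kind="tile",
                    label=ti * n + tj,
                )
            )
    return masks


def make_contour_masks(label_image: np.ndarray) -> list[PixelMask]:
    """Build contour masks from a label image (one mask per positive label).

    Each mask's bounding region is the 25x25 square centered on the labelled
    component's centroid; labelled pixels falling outside that square are
    discarded with a warning.  Empty labels are skipped with a warning.
    """
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise ValueError("label image must be 2D")
    h, w = lab.shape
    half = CONTOUR_REGION_SIZE // 2
    masks: list[PixelMask] = []
    for value in np.unique(lab):
        if value <= 0:
            continue
        rows, cols = np.nonzero(lab == value)
        if rows.size == 0:  # pragma: no cover - unique() only yields present labels
            warnings.warn(f"label {value} has no pixels; skipped")
            continue
        cr = int(round(rows.mean()))
        cc = int(round(cols.mean()))
        keep = (
            (rows >= cr - half)
            & (rows <= cr + half)
            & (cols >= cc - half)
            & (cols <= cc + half)
        )
        if not keep.all():
            warnings.warn(
                f"label {value}: {np.count_nonzero(~keep)} pixels outside the "
                f"{CONTOUR_REGION_SIZE}x{CONTOUR_REGION_SIZE} bounding region "
                "were discarded"
            )
        if not keep.any():
            warnings.warn(f"label {value} left no pixels after truncation; skipped")
            continue
        masks.append(
            PixelMask(rows=rows[keep], cols=cols[keep], kind="contour", label=int(value))
        )
    return masks


class TraceExtractor:
    """Vectorized fluorescence summation over a fixed mask library.

    Precomputes flat pixel indices so each frame costs one gather and one
    segmented reduction.
    """

    def __init__(self, masks: list[PixelMask], frame_shape: tuple[int, int]):
        if not masks:
            raise ValueError("no masks supplied")
        h, w = frame_shape
        for m in masks:
            if m.rows.min() < 0 or m.rows.max() >= h or m.cols.min() < 0 or m.cols.max() >= w:
                raise ValueError("mask extends outside the frame")
        self.masks = masks
        self.frame_shape = frame_shape
        self._flat = np.concatenate([m.rows * w + m.cols for m in masks])
        counts = np.array([m.C for m in masks])
        self._starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.mask_sizes = counts

    def __call__(self, enhanced: np.ndarray) -> np.ndarray:
        """Per-ROI fluorescence sums for one enhanced frame."""
        if enhanced.shape != self.frame_shape:
            raise ValueError("frame shape does not match the mask library")
        vals = enhanced.ravel()[self._flat]
        return np.add.reduceat(vals, self._starts)


def extract_traces(enhanced: np.ndarray, masks: list[PixelMask]) -> np.ndarray:
    """One frame's column of the trace matrix: ``T_roi = sum of mask pixels``."""
    return TraceExtractor(masks, enhanced.shape)(enhanced)


def drop_filter(
    trace: np.ndarray,
    C: int,
    G: float = MAX_PIXEL_INTENSITY,
    q: float = DEFAULT_SENSITIVITY,
    small_mask_limit: int = SMALL_MASK_LIMIT,
) -> np.ndarray:
    """Causal drop filter limiting per-frame decreases of small-mask traces.

    Masks with ``C >= small_mask_limit`` pixels are returned unchanged.
    Otherwise the filtered series obeys ``F(0) = T(0)`` and
    ``F(f) = max(T(f), F(f-1) - delta)`` with ``delta = G * C * q``, so the
    trace can never fall by more than ``delta`` between frames.
    """
    T = np.asarray(trace, dtype=np.float64)
    if C >= small_mask_limit:
        return T.copy()
    delta = G * C * q
    F = np.empty_like(T)
    prev = T[0]
    F[0] = prev
    for f in range(1, T.size):
        prev = max(T[f], prev - delta)
        F[f] = prev
    return F


@dataclass(frozen=True)
class SpikeThreshold:
    """Per-trace event threshold: 2.5 x SD of successive-frame differences
    over the training epoch.  ``degenerate`` marks constant training traces
    (SD = 0), for which events are suppressed."""

    phi: np.ndarray
    degenerate: np.ndarray


def infer_spikes(
    traces: np.ndarray,
    training_range: slice | tuple[int, int],
    multiplier: float = 2.5,
    count_mode: bool = False,
) -> tuple[SpikeThreshold, np.ndarray]:
    """Threshold-crossing event inference on the trace first difference.

    For each trace the threshold ``phi`` is ``multiplier`` times the standard
    deviation of ``T(f) - T(f-1)`` over the training epoch.  An event fires
    at frame ``f`` when the difference strictly exceeds ``phi``.  With
    ``count_mode`` the output is ``floor(max(0, dT) / phi)`` instead of a
    binary indicator.

    Parameters
    ----------
    traces:
        Array of shape (n_traces, n_frames).
    training_range:
        Frames used to estimate ``phi``; must be non-empty and precede the
        frames on which events are to be trusted.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    if isinstance(training_range, tuple):
        training_range = slice(*training_range)
    train = X[:, training_range]
    if train.shape[1] < 2:
        raise ValueError("training range must contain at least two frames")
    diffs = np.diff(train, axis=1)
    sd = diffs.std(axis=1, ddof=0)
    phi = multiplier * sd
    degenerate = sd == 0
    dT = np.diff(X, axis=1, prepend=X[:, :1])
    dT[:, 0] = 0.0  # no prior frame
    if count_mode:
        with np.errstate(divide="ignore", invalid="ignore"):
            events = np.floor(np.maximum(dT, 0.0) / phi[:, None])
        events[~np.isfinite(events)] = 0.0
    else:
        events = (dT > phi[:, None]).astype(np.float64)
    events[degenerate, :] = 0.0
    return SpikeThreshold(phi=phi, degenerate=degenerate), events


def per_frame_decay_fraction(half_decay_s: float = 0.7, frame_interval_s: float = 0.05) -> float:
    """Fractional fluorescence loss per frame of an exponentially decaying
    indicator: ``1 - 0.5 ** (frame_interval / half_decay)``.

    For GCaMP7s (half decay ~0.7 s) at a 50-ms frame this is just under 5%,
    which is why larger single-frame drops can be attributed to motion
    artifact rather than indicator decay.
    """
    if half_decay_s <= 0 or frame_interval_s <= 0:
        raise ValueError("times must be positive")
    return 1.0 - 0.5 ** (frame_interval_s / half_decay_s)
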