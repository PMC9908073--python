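"""Causal rigid motion stabilization against a fixed reference template.

Brain tissue translates under a head-mounted miniscope (persistent *shift*
error when the scope re-seats, transient *jitter* error from inertial brain
motion).  Stage 1 estimates a per-frame integer displacement by correlating
a contrast-filtered 128x128 stabilization window against a reference
template averaged over the first frames of the session, then rigidly
translates the frame back.  Everything is causal: frame ``f`` sees only
frames ``<= f`` and the fixed template.

Conventions
-----------
Displacements are reported as the motion of the image content relative to
the reference: a frame whose content sits 3 pixels to the right of the
template has ``dx = +3``.  ``dx`` indexes columns, ``dy`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "StabilizationConfig",
    "ReferenceTemplate",
    "Displacement",
    "contrast_kernel",
    "contrast_filter",
    "build_reference",
    "estimate_displacement",
    "apply_correction",
    "translate",
    "displacement_features",
]


@dataclass(frozen=True)
class StabilizationConfig:
    """Geometry and filter parameters for motion stabilization.

    ``window_origin`` is the 0-based (row, col) of the top-left corner of
    the stabilization window inside the working frame.
    """

    window_origin: tuple[int, int] = (192, 192)
    window_size: int = 128
    kernel_size: int = 17
    n_reference_frames: int = 1000
    search_radius: int = 16

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.window_size < self.kernel_size:
            raise ValueError("window smaller than contrast kernel")
        if self.search_radius < 0:
            raise ValueError("search_radius must be non-negative")

    def window_slices(self, frame_shape: tuple[int, int]) -> tuple[slice, slice]:
        r0, c0 = self.window_origin
        s = self.window_size
        if r0 < 0 or c0 < 0 or r0 + s > frame_shape[0] or c0 + s > frame_shape[1]:
            raise ValueError(
                f"stabilization window {self.window_origin}+{s} does not fit "
                f"inside frame of shape {frame_shape}"
            )
        return slice(r0, r0 + s), slice(c0, c0 + s)


@dataclass(frozen=True)
class ReferenceTemplate:
    """Mean contrast-filtered stabilization window over the reference epoch."""

    template: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.template)):
            raise ValueError("reference template contains non-finite values")


@dataclass(frozen=True)
class Displacement:
    """Integer rigid displacement of one frame (image relative to template)."""

    dx: int
    dy: int
    low_confidence: bool = False

    @property
    def d(self) -> float:
        return float(np.hypot(self.dx, self.dy))


def contrast_kernel(size: int = 17) -> np.ndarray:
    """Zero-sum local-contrast kernel (difference-of-Gaussians approximation
    to a Laplacian-of-Gaussian), center-positive.

    The two Gaussian widths follow the conventional 1.6 excitation/inhibition
    ratio scaled to the kernel size; the kernel is normalized to sum exactly
    to zero so a constant image yields an all-zero response.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    half = size // 2
    sigma = size / 8.0  # ~2.1 px for the default 17x17 kernel
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = x.astype(float) ** 2 + y.astype(float) ** 2
    g1 = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    s2 = 1.6 * sigma
    g2 = np.exp(-r2 / (2 * s2**2)) / (2 * np.pi * s2**2)
    k = g1 - g2
    k -= k.mean()  # enforce exact zero sum under truncation
    return k


def contrast_filter(window: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Convolve a window with the zero-mean contrast kernel.

    Linear and shift-equivariant on the interior; edges use replication so
    the response stays bounded at the border.
    """
    if kernel is None:
        kernel = contrast_kernel()
    window = np.asarray(window, dtype=np.float64)
    if window.shape[0] < kernel.shape[0] or window.shape[1] < kernel.shape[1]:
        raise ValueError("window smaller than contrast kernel")
    return ndimage.convolve(window, kernel, mode="nearest")


def build_reference(
    frames: Sequence[np.ndarray] | np.ndarray,
    config: StabilizationConfig,
    kernel: np.ndarray | None = None,
) -> ReferenceTemplate:
    """Average the contrast-filtered stabilization windows of the first
    ``config.n_reference_frames`` frames into the reference template.

    Frames beyond the reference epoch are ignored; fewer frames than the
    epoch length is an error.
    """
    n_ref = config.n_reference_frames
    n_avail = len(frames)
    if n_avail < n_ref:
        raise ValueError(
            f"need {n_ref} frames to build the reference, got {n_avail}"
        )
    if kernel is None:
        kernel = contrast_kernel(config.kernel_size)
    rs = cs = None
    acc = None
    for i in range(n_ref):
        frame = np.asarray(frames[i])
        if rs is None:
            rs, cs = config.window_slices(frame.shape)
        filt = contrast_filter(frame[rs, cs], kernel)
        acc = filt if acc is None else acc + filt
    return ReferenceTemplate(template=acc / n_ref, n_frames_used=n_ref)


def _argmax_with_ties(scores: np.ndarray, radius: int) -> tuple[int, int]:
    """Deterministic argmax over a (2R+1)x(2R+1) lag grid.

    Ties at the maximum break toward the smallest ``|dx| + |dy|``, then
    smallest ``dy``, then smallest ``dx``.
    """
    best = scores.max()
    rows, cols = np.nonzero(scores == best)
    dys = rows - radius
    dxs = cols - radius
    order = np.lexsort((dxs, dys, np.abs(dxs) + np.abs(dys)))
    i = order[0]
    return int(dxs[i]), int(dys[i])


def estimate_displacement(
    frame: np.ndarray,
    reference: ReferenceTemplate,
    config: StabilizationConfig,
    kernel: np.ndarray | None = None,
) -> Displacement:
    """Estimate the integer rigid displacement of one frame.

    The contrast-filtered stabilization window is cross-correlated with the
    reference template by zero-padded (linear) FFT correlation; the
    displacement is the integer argmax of the correlation surface within
    ``config.search_radius``.  A textureless (all-zero) filtered window
    cannot be registered and returns (0, 0) flagged low-confidence.
    """
    if kernel is None:
        kernel = contrast_kernel(config.kernel_size)
    rs, cs = config.window_slices(np.asarray(frame).shape)
    filt = contrast_filter(np.asarray(frame)[rs, cs], kernel)
    # a constant window filters to zero up to rounding of the zero-sum
    # kernel; no texture means no registration signal
    if np.abs(filt).max() < 1e-6:
        return Displacement(0, 0, low_confidence=True)
    # full linear cross-correlation: corr[lag] = sum filt[i + lag] * tmpl[i]
    corr = signal.fftconvolve(filt, reference.template[::-1, ::-1], mode="full")
    center = np.array(reference.template.shape) - 1
    R = config.search_radius
    patch = corr[
        center[0] - R : center[0] + R + 1,
        center[1] - R : center[1] + R + 1,
    ]
    dx, dy = _argmax_with_ties(patch, R)
    return Displacement(dx=dx, dy=dy)


def translate(frame: np.ndarray, dx: int, dy: int, fill=0) -> np.ndarray:
    """Shift image content by (+dx columns, +dy rows), filling vacated
    border pixels with ``fill``."""
    out = np.full_like(frame, fill)
    h, w = frame.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def apply_correction(frame: np.ndarray, displacement: Displacement) -> np.ndarray:
    """Undo the estimated rigid motion by translating the frame by
    ``(-dx, -dy)``; vacated border pixels are zero-filled."""
    return translate(frame, -displacement.dx, -displacement.dy, fill=0)


def displacement_features(displacements: Iterable[Displacement]) -> np.ndarray:
    """Per-frame motion feature matrix ``(dx, dy, d, delta_d, |delta_d|)``.

    ``d`` is the Euclidean displacement from the reference alignment and
    ``delta_d`` its frame-to-frame difference (0 for the first frame).
    Used both for motion diagnostics and as the motion-only control
    predictor for behavior decoding.
    """
    dx = np.array([p.dx for p in displacements], dtype=float)
    dy = np.array([p.dy for p in displacements], dtype=float)
    d = np.hypot(dx, dy)
    delta_d = np.diff(d, prepend=d[:1])
    return np.column_stack([dx, dy, d, delta_d, np.abs(delta_d)])
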