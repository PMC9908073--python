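"""Stage 2 — per-frame background removal.

One-photon miniscope frames carry a bright, smoothly varying background of
out-of-focus fluorescence on which the somatic signal rides.  Each
motion-corrected frame is smoothed with a 3x3 mean filter, the background is
estimated by morphological opening (erosion then dilation) with a 19x19 flat
square structuring element, and the background is subtracted from the
smoothed image.  Structures too small to contain the structuring element —
neuron-sized blobs — survive; anything broader is treated as background.

The opening is anti-extensive (background <= smoothed) and idempotent, so
the enhanced image is non-negative and applying the estimator twice changes
nothing.  Both filters replicate edge pixels to avoid dark rims that would
leak into border ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["EnhanceConfig", "enhance_frame", "estimate_background"]


@dataclass(frozen=True)
class EnhanceConfig:
    mean_kernel: int = 3
    structuring_element: int = 19
    clip_floor: float = 0.0
    max_intensity: float = 255.0

    def __post_init__(self) -> None:
        if self.mean_kernel % 2 == 0 or self.structuring_element % 2 == 0:
            raise ValueError("filter sizes must be odd")
        if self.structuring_element <= self.mean_kernel:
            raise ValueError("structuring element must exceed the mean kernel")


def estimate_background(smoothed: np.ndarray, se_size: int = 19) -> np.ndarray:
    """Grayscale opening with a flat square structuring element."""
    eroded = ndimage.grey_erosion(smoothed, size=(se_size, se_size), mode="nearest")
    return ndimage.grey_dilation(eroded, size=(se_size, se_size), mode="nearest")


def enhance_frame(frame: np.ndarray, config: EnhanceConfig = EnhanceConfig()) -> np.ndarray:
    """Smooth, estimate the background by opening, subtract, clip at zero.

    Returns a float array with the input's dimensions, clipped to the 8-bit
    intensity range so downstream trace arithmetic matches the sensor depth.
    """
    f = np.asarray(frame, dtype=np.float64)
    smoothed = ndimage.uniform_filter(f, size=config.mean_kernel, mode="nearest")
    background = estimate_background(smoothed, config.structuring_element)
    enhanced = np.clip(smoothed - background, config.clip_floor, config.max_intensity)
    return enhanced
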