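"""End-to-end orchestration: the virtual-sensor streaming loop.

Frames are processed strictly in arrival order and causally, mirroring the
five-step session protocol of a real closed-loop experiment:

1. the first ``n_reference_frames`` frames build the motion reference
   template (no correction is applied during this epoch);
2. every subsequent frame is registered against the template, rigidly
   corrected, background-removed, and summed over the ROI masks;
3. the decoder is trained on the training split of the extracted traces;
4. predictions and TTL outputs are emitted for the test split;
5. all artifacts (traces, displacements, predictions, metrics) are written
   to disk.

Correctness is defined frame-wise, not wall-clock-wise: processing a stored
stack frame by frame is bit-identical to processing it in one call, which
is what lets a stored session stand in for the live sensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import metrics as _metrics
from .decode import (
    GrayCode,
    make_gray_code,
    predict_position_series,
    train_position_decoder,
    shift_control,
)
from .enhance import EnhanceConfig, enhance_frame
from .stabilize import (
    Displacement,
    ReferenceTemplate,
    StabilizationConfig,
    apply_correction,
    contrast_filter,
    contrast_kernel,
    estimate_displacement,
)
from .traces import (
    DEFAULT_SENSITIVITY,
    MAX_PIXEL_INTENSITY,
    SMALL_MASK_LIMIT,
    TraceExtractor,
    make_contour_masks,
    make_tile_masks,
)

logger = logging.getLogger(__name__)

__all__ = ["SessionConfig", "FrameProcessor", "StreamResult", "process_frames", "stream_session"]


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of one streaming session.

    ``training_split`` is the frame index at which training data end and
    the test epoch begins; ``None`` means half the session.  ``ttl_rules``
    maps TTL line index to the set of predicted position bins (or behavior
    labels) that drive the line high.
    """

    fps: float = 20.0
    frame_shape: tuple[int, int] = (512, 512)
    mask_mode: str = "contour-free"  # or "contour-based"
    tile: int = 16
    stabilization: StabilizationConfig = field(default_factory=StabilizationConfig)
    enhancement: EnhanceConfig = field(default_factory=EnhanceConfig)
    motion_correction: bool = True
    n_position_bins: int = 24
    track_length_cm: float = 250.0
    training_split: int | None = None
    training_start: int | None = None  # default: end of the reference epoch
    svm_C: float = 1.0
    tolerance_cm: float = 30.0
    ttl_rules: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mask_mode not in ("contour-free", "contour-based"):
            raise ValueError(f"unknown mask mode {self.mask_mode!r}")
        # geometry must fit the working frame
        self.stabilization.window_slices(self.frame_shape)


class FrameProcessor:
    """Causal per-frame processing core (Stages 1-3).

    ``push(frame)`` consumes the next frame and returns
    ``(Displacement, trace_column)``.  While the reference epoch is still
    filling, displacement is (0, 0) flagged low-confidence and no
    correction is applied; the template is frozen as soon as the epoch
    completes.  Feeding frames one at a time is bit-identical to feeding
    the whole stack.
    """

    def __init__(self, config: SessionConfig, masks):
        self.config = config
        self.masks = masks
        self.extract = TraceExtractor(masks, config.frame_shape)
        self._kernel = contrast_kernel(config.stabilization.kernel_size)
        self._acc = None
        self._n_seen = 0
        self.reference: ReferenceTemplate | None = None
        self.displacements: list[Displacement] = []
        self.trace_columns: list[np.ndarray] = []
        # causal drop filter for small contour masks: cap on the per-frame
        # decrease, infinite (no filtering) for tiles and large contours
        sizes = self.extract.mask_sizes.astype(float)
        small = np.array(
            [m.kind == "contour" and m.C < SMALL_MASK_LIMIT for m in masks]
        )
        self._delta = np.where(
            small, MAX_PIXEL_INTENSITY * sizes * DEFAULT_SENSITIVITY, np.inf
        )
        self._prev_filtered: np.ndarray | None = None

    def _window(self, frame):
        rs, cs = self.config.stabilization.window_slices(frame.shape)
        return frame[rs, cs]

    def push(self, frame: np.ndarray) -> tuple[Displacement, np.ndarray]:
        frame = np.asarray(frame)
        if frame.shape != self.config.frame_shape:
            raise ValueError(
                f"frame {self._n_seen}: shape {frame.shape} does not match "
                f"configured {self.config.frame_shape}"
            )
        stab = self.config.stabilization
        if self.reference is None:
            filt = contrast_filter(self._window(frame), self._kernel)
            self._acc = filt if self._acc is None else self._acc + filt
            disp = Displacement(0, 0, low_confidence=True)
            if self._n_seen + 1 == stab.n_reference_frames:
                self.reference = ReferenceTemplate(
                    template=self._acc / stab.n_reference_frames,
                    n_frames_used=stab.n_reference_frames,
                )
                self._acc = None
        else:
            disp = estimate_displacement(frame, self.reference, stab, self._kernel)
        corrected = (
            apply_correction(frame, disp) if self.config.motion_correction else frame
        )
        enhanced = enhance_frame(corrected, self.config.enhancement)
        col = self.extract(enhanced)
        if self._prev_filtered is not None:
            col = np.maximum(col, self._prev_filtered - self._delta)
        self._prev_filtered = col
        self.displacements.append(disp)
        self.trace_columns.append(col)
        self._n_seen += 1
        return disp, col

    @property
    def traces(self) -> np.ndarray:
        """Trace matrix (n_rois, n_frames) over the frames seen so far."""
        return np.array(self.trace_columns).T


def _build_masks(config: SessionConfig, label_image=None):
    if config.mask_mode == "contour-free":
        return make_tile_masks(frame_size=config.frame_shape[0], tile=config.tile)
    if label_image is None:
        raise ValueError("contour-based mask mode requires a label image")
    return make_contour_masks(label_image)


def process_frames(frames, config: SessionConfig, masks=None, label_image=None):
    """Run Stages 1-3 over a whole stack; returns the FrameProcessor."""
    if masks is None:
        masks = _build_masks(config, label_image)
    proc = FrameProcessor(config, masks)
    for f, frame in enumerate(frames):
        try:
            proc.push(frame)
        except ValueError as err:
            raise ValueError(f"frame {f}: {err}") from err
    return proc


@dataclass
class StreamResult:
    """Everything one streaming session produces."""

    traces: np.ndarray
    displacements: list
    predictions: np.ndarray | None
    test_range: slice | None
    ttl_log: pd.DataFrame | None
    metrics: dict
    model: object | None = None


def _apply_ttl(predictions: np.ndarray, frame_indices: np.ndarray, rules: dict) -> pd.DataFrame:
    """Logic-mapper emulation: one row per post-training frame, one binary
    column per TTL line."""
    data = {"frame_index": frame_indices, "predicted": predictions}
    for line, targets in sorted(rules.items()):
        targets = set(targets)
        data[f"ttl_{line}"] = np.array(
            [1 if p in targets else 0 for p in predictions], dtype=int
        )
    return pd.DataFrame(data)


def stream_session(
    frames,
    config: SessionConfig,
    position_bins: np.ndarray | None = None,
    label_image: np.ndarray | None = None,
    masks=None,
    output_dir=None,
    run_shift_control: bool = False,
) -> StreamResult:
    """Full session: Stages 1-3 streaming, decoder training, test-epoch
    prediction, TTL mapping, and evaluation.

    Parameters
    ----------
    frames:
        Frame stack (array or sequence) — the stored stand-in for the live
        sensor.
    position_bins:
        Per-frame true position bin (1-based).  When given, a position
        decoder is trained on the training split and evaluated on the test
        split; otherwise only traces and displacements are produced.
    output_dir:
        When given, traces, displacements, predictions, TTL log, metrics,
        and a config echo are written there.
    """
    n_frames = len(frames)
    proc = process_frames(frames, config, masks=masks, label_image=label_image)
    traces = proc.traces
    result_metrics: dict = {"n_frames": n_frames, "n_traces": traces.shape[0]}

    predictions = None
    ttl_log = None
    test_range = None
    model = None
    if position_bins is not None:
        position_bins = np.asarray(position_bins)
        if position_bins.size != n_frames:
            raise ValueError("position series length differs from frame count")
        split = config.training_split or n_frames // 2
        start = (
            config.training_start
            if config.training_start is not None
            else min(config.stabilization.n_reference_frames, split)
        )
        training_range = slice(start, split)
        test_range = slice(split, n_frames)
        code = make_gray_code(config.n_position_bins)
        model = train_position_decoder(
            traces, position_bins, code, training_range, C=config.svm_C
        )
        predictions = predict_position_series(model, traces[:, test_range].T)
        geometry = _metrics.BinGeometry(config.track_length_cm, config.n_position_bins)
        lam, lam_bar, rho = _metrics.position_metrics(
            position_bins[test_range], predictions, geometry, config.tolerance_cm
        )
        result_metrics.update(
            {"lambda_mean_cm": lam_bar, "hit_rate_pct": rho, "test_frames": predictions.size}
        )
        d_series = np.array([p.d for p in proc.displacements])
        omega = _metrics.motion_artifact_score(
            lam, d_series[test_range], position_bins[test_range]
        )
        result_metrics["motion_artifact_score"] = omega
        if run_shift_control:
            ctrl = shift_control(
                traces,
                position_bins,
                code,
                training_range,
                test_range,
                geometry,
                C=config.svm_C,
                tolerance_cm=config.tolerance_cm,
            )
            result_metrics["shift_control"] = ctrl
        ttl_log = _apply_ttl(
            predictions, np.arange(split, n_frames), config.ttl_rules
        )
        logger.info(
            "session decoded: lambda_mean=%.1f cm, hit rate=%.1f%%", lam_bar, rho
        )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_traces(out / "traces.csv", traces)
        _io.write_displacements(out / "displacements.csv", proc.displacements)
        if predictions is not None:
            _io.write_series_csv(out / "predictions.csv", "predicted_bin", predictions)
        if ttl_log is not None:
            ttl_log.to_csv(out / "ttl_log.csv", index=False)
        _io.write_json(out / "metrics.json", result_metrics)
        _io.write_json(out / "config.json", config)

    return StreamResult(
        traces=traces,
        displacements=proc.displacements,
        predictions=predictions,
        test_range=test_range,
        ttl_log=ttl_log,
        metrics=result_metrics,
        model=model,
    )
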