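"""Synthetic miniscope sessions with ground truth.

Emulates what a head-mounted one-photon miniscope sees while a rat runs a
linear track or performs an instrumental task: spatially tuned neurons
(place cells) rendered as truncated Gaussian blobs, exponential-decay
calcium indicator dynamics, a smooth polynomial background, scripted rigid
motion of the image (persistent *shift* and transient *jitter* events), and
additive sensor noise — together with the ground-truth traces,
displacements, and labels every downstream stage is tested against.

The generator is fully deterministic given its seed, and deliberately
simple: integer-pixel rigid translation only (so displacement recovery is
exactly checkable), no optics, no photobleaching, no spiking biophysics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "GroundTruthCell",
    "MotionScript",
    "MotionEvent",
    "SyntheticSession",
    "FieldSpec",
    "NoiseParams",
    "BackgroundSpec",
    "BehaviorTiming",
    "generate_trajectory",
    "generate_place_cell_population",
    "compute_true_traces",
    "render_session",
    "generate_behavior_session",
    "position_bin_index",
]

#: Default circularized-track geometry: 250-cm track, 24 bins (12/direction).
DEFAULT_TRACK_CM = 250.0
DEFAULT_N_BINS = 24

#: Cap on running speed, cm/s.
MAX_SPEED_CM_S = 150.0

#: Calcium indicator half decay time, seconds (GCaMP7s-like).
DEFAULT_HALF_DECAY_S = 0.7

RIGHTWARD = "rightward"
LEFTWARD = "leftward"


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def position_bin_index(
    position_cm: np.ndarray,
    direction: np.ndarray,
    L_cm: float = DEFAULT_TRACK_CM,
    K: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Deterministic circularized bin index in ``1..K``.

    The out-and-back path is unrolled onto a loop of length ``2 L``:
    rightward frames map to loop coordinate ``x`` (bins ``1..K/2``),
    leftward frames to ``2L - x`` (bins ``K/2+1..K``).
    """
    position_cm = np.asarray(position_cm, dtype=np.float64)
    direction = np.asarray(direction)
    half = K // 2
    width = L_cm / half
    right = np.clip(position_cm // width + 1, 1, half)
    left = np.clip(half + (L_cm - position_cm) // width + 1, half + 1, K)
    return np.where(direction == RIGHTWARD, right, left).astype(int)


@dataclass(frozen=True)
class Trajectory:
    """Per-frame position on the linear track.

    ``position_cm`` lies in ``[0, L_cm]``; ``direction`` is the running
    direction label; ``bin_index`` is the circularized position bin.
    """

    position_cm: np.ndarray
    direction: np.ndarray
    fps: float
    L_cm: float = DEFAULT_TRACK_CM
    K: int = DEFAULT_N_BINS
    bin_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.bin_index is None:
            object.__setattr__(
                self,
                "bin_index",
                position_bin_index(self.position_cm, self.direction, self.L_cm, self.K),
            )

    @property
    def n_frames(self) -> int:
        return self.position_cm.size


def generate_trajectory(
    L_cm: float = DEFAULT_TRACK_CM,
    n_frames: int = 8000,
    fps: float = 20.0,
    speed_cm_s: float = 50.0,
    dwell_s: float = 0.5,
    speed_jitter: float = 0.0,
    K: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> Trajectory:
    """Alternating end-to-end runs at constant speed with end-of-track dwell.

    ``speed_jitter`` (fraction of the nominal speed) adds per-frame
    multiplicative speed noise; the instantaneous speed is capped at
    150 cm/s.  During the dwell at a track end the direction label keeps the
    direction of the completed run until the next run starts.
    """
    if L_cm <= 0 or fps <= 0:
        raise ValueError("track length and frame rate must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if speed_cm_s <= 0 or dwell_s < 0:
        raise ValueError("speed must be positive and dwell non-negative")
    rng = np.random.default_rng(seed)
    dwell_frames = int(round(dwell_s * fps))
    pos = np.empty(n_frames)
    direction = np.empty(n_frames, dtype=object)
    x = 0.0
    heading = 1  # +1 rightward, -1 leftward
    dwell_left = 0
    for f in range(n_frames):
        pos[f] = x
        direction[f] = RIGHTWARD if heading > 0 else LEFTWARD
        if dwell_left > 0:
            dwell_left -= 1
            if dwell_left == 0:
                heading = -heading
            continue
        v = speed_cm_s
        if speed_jitter > 0:
            v *= 1.0 + speed_jitter * rng.standard_normal()
        v = float(np.clip(v, 0.0, MAX_SPEED_CM_S))
        x += heading * v / fps
        if x >= L_cm:
            x = L_cm
            dwell_left = max(dwell_frames, 1)
        elif x <= 0.0:
            x = 0.0
            dwell_left = max(dwell_frames, 1)
    return Trajectory(
        position_cm=pos, direction=direction.astype(str), fps=fps, L_cm=L_cm, K=K
    )


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Population-level defaults for synthetic cells.

    ``field_width_cm`` is the Gaussian sigma of the spatial tuning;
    ``radius_px`` truncates the footprint Gaussian (sigma = radius / 2).
    ``amplitude`` is the peak activation in 8-bit fluorescence units.
    """

    radius_px: int = 6
    amplitude: float = 60.0
    field_width_cm: float = 12.0
    decay_halftime_s: float = DEFAULT_HALF_DECAY_S
    margin_px: int = 40
    center_jitter_px: float = 3.0

    def __post_init__(self) -> None:
        if self.field_width_cm <= 0 or self.decay_halftime_s <= 0:
            raise ValueError("field width and decay half-time must be positive")


@dataclass(frozen=True)
class GroundTruthCell:
    """One synthetic neuron: a spatial footprint plus place tuning.

    The footprint is a truncated 2D Gaussian patch whose top-left corner in
    the frame is ``origin``; weights are non-negative.
    """

    footprint: np.ndarray
    origin: tuple[int, int]
    field_center_cm: float
    field_width_cm: float
    direction_pref: str
    amplitude: float
    decay_halftime_s: float = DEFAULT_HALF_DECAY_S

    def __post_init__(self) -> None:
        if np.any(self.footprint < 0):
            raise ValueError("footprint weights must be non-negative")
        if self.decay_halftime_s <= 0:
            raise ValueError("decay half-time must be positive")

    def paint(self, canvas: np.ndarray, scale: float) -> None:
        """Add ``scale * footprint`` into the frame-sized canvas in place."""
        r0, c0 = self.origin
        h, w = self.footprint.shape
        canvas[r0 : r0 + h, c0 : c0 + w] += scale * self.footprint


def _gaussian_patch(radius: int) -> np.ndarray:
    sigma = radius / 2.0
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    patch = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    patch[x**2 + y**2 > radius**2] = 0.0
    return patch


def generate_place_cell_population(
    n_cells: int,
    field_spec: FieldSpec = FieldSpec(),
    seed: int = 0,
    frame_shape: tuple[int, int] = (512, 512),
    L_cm: float = DEFAULT_TRACK_CM,
) -> list[GroundTruthCell]:
    """Cells whose place-field centers tile the track, directions alternating.

    Footprint centers are laid out on a near-square grid over the frame
    interior (footprints may overlap after jitter; disjointness is not
    required).  A footprint that would exceed the frame bounds is rejected.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    patch = _gaussian_patch(field_spec.radius_px)
    h, w = frame_shape
    m = field_spec.margin_px
    side = int(np.ceil(np.sqrt(n_cells)))
    grid_r = np.linspace(m, h - 1 - m, side)
    grid_c = np.linspace(m, w - 1 - m, side)
    centers_cm = (np.arange(n_cells) + 0.5) * L_cm / np.ceil(n_cells / 2)
    cells = []
    for i in range(n_cells):
        cr = grid_r[i // side] + field_spec.center_jitter_px * rng.standard_normal()
        cc = grid_c[i % side] + field_spec.center_jitter_px * rng.standard_normal()
        r0 = int(round(cr)) - field_spec.radius_px
        c0 = int(round(cc)) - field_spec.radius_px
        if r0 < 0 or c0 < 0 or r0 + patch.shape[0] > h or c0 + patch.shape[1] > w:
            raise ValueError(
                f"cell {i}: footprint at ({r0}, {c0}) exceeds frame bounds"
            )
        cells.append(
            GroundTruthCell(
                footprint=patch,
                origin=(r0, c0),
                field_center_cm=float(centers_cm[i] % L_cm),
                field_width_cm=field_spec.field_width_cm,
                direction_pref=RIGHTWARD if i % 2 == 0 else LEFTWARD,
                amplitude=field_spec.amplitude,
                decay_halftime_s=field_spec.decay_halftime_s,
            )
        )
    return cells


def compute_true_traces(
    cells: list[GroundTruthCell], trajectory: Trajectory
) -> np.ndarray:
    """Ground-truth activation of every cell at every frame.

    The instantaneous drive is a Gaussian function of the distance between
    the animal and the cell's place-field center (zero when running in the
    non-preferred direction); the calcium signal follows the drive upward
    instantly and decays exponentially with the indicator half-time:
    ``a(f) = max(drive(f), a(f-1) * 0.5 ** (1 / (halftime * fps)))``.
    """
    n = trajectory.n_frames
    out = np.zeros((len(cells), n))
    for ci, cell in enumerate(cells):
        drive = cell.amplitude * np.exp(
            -((trajectory.position_cm - cell.field_center_cm) ** 2)
            / (2 * cell.field_width_cm**2)
        )
        drive = np.where(trajectory.direction == cell.direction_pref, drive, 0.0)
        decay = 0.5 ** (1.0 / (cell.decay_halftime_s * trajectory.fps))
        a = 0.0
        for f in range(n):
            a = max(drive[f], a * decay)
            out[ci, f] = a
    return out


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionEvent:
    """One scripted motion event.

    ``kind`` is ``"shift"`` (the offset persists to the session end) or
    ``"jitter"`` (the offset lasts ``duration`` frames, then the image
    returns to its pre-event alignment).
    """

    kind: str
    start: int
    dx: int
    dy: int
    duration: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "jitter"):
            raise ValueError(f"unknown motion event kind {self.kind!r}")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")


@dataclass(frozen=True)
class MotionScript:
    """Per-frame true integer-pixel rigid translation of the image."""

    dx: np.ndarray
    dy: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.dx.size

    @classmethod
    def still(cls, n_frames: int) -> "MotionScript":
        return cls(np.zeros(n_frames, dtype=int), np.zeros(n_frames, dtype=int))

    @classmethod
    def from_events(cls, n_frames: int, events: list[MotionEvent]) -> "MotionScript":
        """Compose shift (persistent) and jitter (transient) events.

        Jitter offsets add on top of the running shift baseline and return
        to it when the event ends.
        """
        base_dx = np.zeros(n_frames, dtype=int)
        base_dy = np.zeros(n_frames, dtype=int)
        jit_dx = np.zeros(n_frames, dtype=int)
        jit_dy = np.zeros(n_frames, dtype=int)
        for ev in events:
            if ev.start >= n_frames:
                continue
            if ev.kind == "shift":
                base_dx[ev.start :] += ev.dx
                base_dy[ev.start :] += ev.dy
            else:
                stop = min(ev.start + ev.duration, n_frames)
                jit_dx[ev.start : stop] += ev.dx
                jit_dy[ev.start : stop] += ev.dy
        return cls(base_dx + jit_dx, base_dy + jit_dy)

    def d(self) -> np.ndarray:
        return np.hypot(self.dx.astype(float), self.dy.astype(float))

    def abs_delta_d(self) -> np.ndarray:
        d = self.d()
        return np.abs(np.diff(d, prepend=d[:1]))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundSpec:
    """Static background: a low-order 2D polynomial plus smooth anatomical
    texture, with optional slow sinusoidal temporal drift.

    The texture term (Gaussian-smoothed noise, standard deviation
    ``texture_amp`` intensity units at correlation length ``texture_sigma``
    pixels) stands in for vessels and neuropil — the stable anatomical
    features a stabilization window is chosen to contain.  Without it a
    contrast filter would see nothing but the time-varying cells and
    registration against a fixed template would be ill-posed.
    """

    offset: float = 30.0
    gx: float = 10.0
    gy: float = 6.0
    gxx: float = -4.0
    gyy: float = -4.0
    texture_amp: float = 15.0
    texture_sigma: float = 2.5
    texture_seed: int = 0
    drift_amp: float = 0.0
    drift_period_frames: int = 2000

    def render(self, frame_shape: tuple[int, int]) -> np.ndarray:
        from scipy import ndimage as _ndi

        h, w = frame_shape
        y, x = np.mgrid[0:h, 0:w]
        xn = x / max(w - 1, 1) - 0.5
        yn = y / max(h - 1, 1) - 0.5
        bg = (
            self.offset
            + self.gx * xn
            + self.gy * yn
            + self.gxx * xn**2
            + self.gyy * yn**2
        )
        if self.texture_amp > 0:
            rng = np.random.default_rng(self.texture_seed)
            tex = _ndi.gaussian_filter(rng.standard_normal(frame_shape), self.texture_sigma)
            bg = bg + self.texture_amp * tex / tex.std()
        return bg

    def drift_factor(self, f: int) -> float:
        if self.drift_amp == 0:
            return 1.0
        return 1.0 + self.drift_amp * np.sin(2 * np.pi * f / self.drift_period_frames)


@dataclass(frozen=True)
class NoiseParams:
    """Additive i.i.d. Gaussian sensor noise, clipped with the frame to
    the 8-bit range."""

    sigma: float = 2.0
    saturation_limit: float = 0.01


@dataclass
class SyntheticSession:
    """A complete synthetic recording with its ground truth."""

    frames: np.ndarray | None
    trajectory: Trajectory | None
    cells: list[GroundTruthCell]
    motion: MotionScript
    true_traces: np.ndarray
    seed: int
    behavior_labels: np.ndarray | None = None
    frame_shape: tuple[int, int] = (512, 512)

    @property
    def n_frames(self) -> int:
        return self.true_traces.shape[1]

    def footprint_label_image(self, threshold: float = 0.5) -> np.ndarray:
        """Label image of footprints thresholded at ``threshold`` x max,
        for contour-mask construction from ground truth."""
        lab = np.zeros(self.frame_shape, dtype=np.int32)
        for i, cell in enumerate(self.cells, start=1):
            mask = cell.footprint >= threshold * cell.footprint.max()
            r0, c0 = cell.origin
            h, w = cell.footprint.shape
            region = lab[r0 : r0 + h, c0 : c0 + w]
            region[mask] = i
        return lab


def render_session(
    cells: list[GroundTruthCell],
    trajectory: Trajectory,
    motion: MotionScript | None = None,
    noise_params: NoiseParams | None = None,
    background: BackgroundSpec | None = None,
    seed: int = 0,
    frame_shape: tuple[int, int] = (512, 512),
    true_traces: np.ndarray | None = None,
    behavior_labels: np.ndarray | None = None,
    render_frames: bool = True,
) -> SyntheticSession:
    """Render frames = clip(background + sum(activation x footprint), 0..255),
    rigidly translated by the motion script, plus sensor noise.

    All per-frame components must agree on the frame count.  With
    ``render_frames=False`` only the ground truth is produced (cheap
    sessions for decoder-level tests).
    """
    from .stabilize import translate  # integer-pixel rigid translation

    n = trajectory.n_frames if trajectory is not None else true_traces.shape[1]
    if motion is None:
        motion = MotionScript.still(n)
    if background is None:
        background = BackgroundSpec()
    if noise_params is None:
        noise_params = NoiseParams()
    if motion.n_frames != n:
        raise ValueError("motion script frame count differs from trajectory")
    if true_traces is None:
        true_traces = compute_true_traces(cells, trajectory)
    if true_traces.shape != (len(cells), n):
        raise ValueError("true_traces shape inconsistent with cells/frames")
    if behavior_labels is not None and len(behavior_labels) != n:
        raise ValueError("behavior labels frame count differs from trajectory")

    frames = None
    if render_frames:
        rng = np.random.default_rng(seed)
        bg = background.render(frame_shape)
        frames = np.empty((n,) + frame_shape, dtype=np.uint8)
        saturated = 0
        for f in range(n):
            canvas = bg * background.drift_factor(f)
            for ci, cell in enumerate(cells):
                if true_traces[ci, f] > 0:
                    cell.paint(canvas, true_traces[ci, f])
            canvas = translate(canvas, int(motion.dx[f]), int(motion.dy[f]), fill=0)
            if noise_params.sigma > 0:
                canvas = canvas + noise_params.sigma * rng.standard_normal(frame_shape)
            np.clip(canvas, 0, 255, out=canvas)
            frame = canvas.astype(np.uint8)
            saturated += np.count_nonzero(frame == 255)
            frames[f] = frame
        frac = saturated / frames.size
        if frac > noise_params.saturation_limit:
            warnings.warn(
                f"saturation fraction {frac:.3f} exceeds limit "
                f"{noise_params.saturation_limit:.3f}"
            )
            logger.warning("rendered session saturation fraction %.3f", frac)
    return SyntheticSession(
        frames=frames,
        trajectory=trajectory,
        cells=cells,
        motion=motion,
        true_traces=true_traces,
        seed=seed,
        behavior_labels=behavior_labels,
        frame_shape=frame_shape,
    )


# ---------------------------------------------------------------------------
# Instrumental behavior sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorTiming:
    """Trial timing for the instrumental-task emulation, in seconds.

    Pre-trial frames cover a 1-s window before the center touch; reward
    retrieval covers a 2-s window after magazine entry; choices span the
    interval between center touch and choice touch.

    With behavior-locked jitter enabled, a rigid offset of 2..``jitter_px``
    pixels in a random direction accompanies a fraction ``jitter_prob`` of
    reward onsets and lasts ``jitter_duration`` frames — sustained brain
    motion while the animal retrieves food from the magazine.
    """

    fps: float = 20.0
    pre_trial_s: float = 1.0
    choice_s: float = 1.5
    reward_s: float = 2.0
    #: kept longer than the other categories combined, as in the task it
    #: emulates, so "no event" is the dominant state
    intertrial_s: float = 6.0
    #: uniform range of the delay between choice touch and magazine entry
    #: (the animal must travel to the magazine); these frames carry no
    #: event label, so reward onset is not a fixed latency after choice
    magazine_delay_s: tuple[float, float] = (0.5, 3.0)
    p_correct: float = 0.9
    jitter_prob: float = 0.6
    jitter_px: int = 5
    #: retrieval motion spans the whole 2-s reward window: the head stays
    #: down at the magazine while the animal works the food pellet
    jitter_duration: int = 40
    #: uniform frame range after reward onset at which retrieval motion
    #: starts (the head keeps moving while the animal works the magazine)
    jitter_onset_frames: tuple[int, int] = (0, 4)


def _behavior_label_series(
    n_trials: int, timing: BehaviorTiming, rng: np.random.Generator
) -> tuple[np.ndarray, int, list[tuple[int, None]]]:
    """Lay out label segments trial by trial.

    Returns the label series, the frame count, and the reward-onset frames.
    Frames default to intertrial; event windows are written in temporal
    order so a later event truncates an earlier one if windows overlap.
    """
    fps = timing.fps
    frames_per = lambda s: max(int(round(s * fps)), 1)
    segments = []  # (label, n_frames) in temporal order
    reward_onsets = []
    cursor = 0

    def emit(label, nf):
        nonlocal cursor
        segments.append((label, cursor, cursor + nf))
        cursor += nf

    emit("intertrial", frames_per(timing.intertrial_s))
    for _ in range(n_trials):
        emit("pre-trial", frames_per(timing.pre_trial_s))
        correct = rng.random() < timing.p_correct
        emit("correct choice" if correct else "incorrect choice", frames_per(timing.choice_s))
        if correct:
            lo, hi = timing.magazine_delay_s
            delay = lo + (hi - lo) * rng.random()
            if delay > 0:
                emit("intertrial", frames_per(delay))
            reward_onsets.append((cursor, None))
            emit("reward retrieval", frames_per(timing.reward_s))
        emit("intertrial", frames_per(timing.intertrial_s))
    n_frames = cursor
    labels = np.full(n_frames, "intertrial", dtype=object)
    for label, s, e in segments:
        labels[s:e] = label  # later windows overwrite earlier on overlap
    return labels.astype(str), n_frames, reward_onsets


def generate_behavior_session(
    n_trials: int,
    timing: BehaviorTiming = BehaviorTiming(),
    seed: int = 0,
    n_cells: int = 20,
    frame_shape: tuple[int, int] = (256, 256),
    behavior_locked_jitter: bool = True,
    random_jitter_events: int = 0,
    field_spec: FieldSpec | None = None,
    noise_params: NoiseParams | None = None,
    trace_noise: float = 6.0,
    amplitude_drift: float = 0.0,
    encode_categories: tuple[str, ...] | None = None,
    render_frames: bool = True,
) -> SyntheticSession:
    """Synthetic instrumental-task session with category-tuned cells.

    Each cell prefers one of the five behavior categories and is driven
    while that category is active (calcium decays with the indicator
    half-time otherwise), with additive drive noise ``trace_noise``.  With
    ``behavior_locked_jitter`` a transient motion event accompanies a
    fraction of reward-retrieval onsets, emulating brain motion during food
    retrieval from the magazine; ``random_jitter_events`` adds
    behavior-independent jitter instead/in addition (control condition).

    ``encode_categories`` restricts which categories the cells prefer
    (default: all five).  Excluding a category makes that event invisible
    to the calcium signal, isolating whatever non-neural pathways (motion
    artifact) could still predict it.

    ``amplitude_drift`` adds representational drift: each cell's gain
    ramps linearly to a random factor in ``1 +- amplitude_drift`` by the
    session end, so a decoder trained on the early epoch generalizes only
    partially to the late epoch — the dominant failure mode of real
    session-length recordings.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    labels, n_frames, reward_onsets = _behavior_label_series(n_trials, timing, rng)

    events: list[MotionEvent] = []
    if behavior_locked_jitter:
        lo, hi = timing.jitter_onset_frames
        for onset, _ in reward_onsets:
            if rng.random() < timing.jitter_prob:
                amp = int(rng.integers(2, timing.jitter_px + 1))
                angle = rng.random() * 2 * np.pi
                dx = int(round(amp * np.cos(angle)))
                dy = int(round(amp * np.sin(angle)))
                if dx == 0 and dy == 0:
                    dx = amp
                start = onset + int(rng.integers(lo, hi + 1))
                events.append(MotionEvent("jitter", start, dx, dy, timing.jitter_duration))
    for _ in range(random_jitter_events):
        start = int(rng.integers(0, max(n_frames - timing.jitter_duration, 1)))
        amp = int(rng.integers(2, timing.jitter_px + 1))
        angle = rng.random() * 2 * np.pi
        events.append(
            MotionEvent(
                "jitter",
                start,
                int(round(amp * np.cos(angle))) or amp,
                int(round(amp * np.sin(angle))),
                timing.jitter_duration,
            )
        )
    motion = MotionScript.from_events(n_frames, events)

    if field_spec is None:
        field_spec = FieldSpec(margin_px=30, amplitude=50.0)
    patch = _gaussian_patch(field_spec.radius_px)
    h, w = frame_shape
    m = field_spec.margin_px
    side = int(np.ceil(np.sqrt(n_cells)))
    grid_r = np.linspace(m, h - 1 - m, side)
    grid_c = np.linspace(m, w - 1 - m, side)
    from .decode import BEHAVIOR_CATEGORIES

    if encode_categories is None:
        encode_categories = BEHAVIOR_CATEGORIES
    cells = []
    for i in range(n_cells):
        r0 = int(round(grid_r[i // side])) - field_spec.radius_px
        c0 = int(round(grid_c[i % side])) - field_spec.radius_px
        cells.append(
            GroundTruthCell(
                footprint=patch,
                origin=(r0, c0),
                field_center_cm=0.0,
                field_width_cm=field_spec.field_width_cm,
                direction_pref=encode_categories[i % len(encode_categories)],
                amplitude=field_spec.amplitude,
                decay_halftime_s=field_spec.decay_halftime_s,
            )
        )

    decay = 0.5 ** (1.0 / (field_spec.decay_halftime_s * timing.fps))
    true_traces = np.zeros((n_cells, n_frames))
    ramp = np.arange(n_frames) / max(n_frames - 1, 1)
    for ci, cell in enumerate(cells):
        gain = np.ones(n_frames)
        if amplitude_drift > 0:
            end_factor = 1.0 + amplitude_drift * (2.0 * rng.random() - 1.0)
            gain = 1.0 + (end_factor - 1.0) * ramp
        drive = np.where(labels == cell.direction_pref, cell.amplitude * gain, 0.0)
        if trace_noise > 0:
            drive = np.clip(
                drive + trace_noise * rng.standard_normal(n_frames), 0.0, None
            )
        a = 0.0
        for f in range(n_frames):
            a = max(drive[f], a * decay)
            true_traces[ci, f] = a

    return render_session(
        cells=cells,
        trajectory=None,
        motion=motion,
        noise_params=noise_params,
        seed=seed,
        frame_shape=frame_shape,
        true_traces=true_traces,
        behavior_labels=labels,
        render_frames=render_frames,
    )
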