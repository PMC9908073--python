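"""Stage 4 — population decoding of position and behavior from calcium
trace vectors.

Position decoding uses an error-correcting output code: the K = 24
circularized track bins are represented by a cyclic Gray code with
M = K/2 = 12 binary output units, each backed by an L2-regularized linear
classifier over the N traces.  A frame's decoded bin is the code column
whose codeword most closely matches the real-valued classifier output
vector (maximal inner product, reducing to minimal Hamming distance on hard
signs).  Adjacent track bins differ in exactly one output unit, so a single
misfiring unit costs at most one bin of error.

Behavior decoding uses a fixed binary tree of linear classifiers over the
five mutually exclusive trial categories, with causal five-frame majority
smoothing of the predicted labels.  A motion-only control predictor
(dx, dy, d, delta_d, |delta_d|) quantifies how much of the apparent
decoding performance could be driven by motion artifact rather than
calcium activity, and a circular-shift control gives the chance level of
position decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "GrayCode",
    "DecoderModel",
    "BehaviorTree",
    "make_gray_code",
    "train_position_decoder",
    "predict_position",
    "predict_position_series",
    "train_behavior_tree",
    "predict_behavior",
    "majority_smooth",
    "shift_control",
    "BEHAVIOR_CATEGORIES",
    "DEFAULT_SHIFTS",
]

BEHAVIOR_CATEGORIES = (
    "pre-trial",
    "correct choice",
    "incorrect choice",
    "reward retrieval",
    "intertrial",
)

#: Frame offsets used for the circular-shift chance control.
DEFAULT_SHIFTS = (500, 1000, 1500, 2000, 2500)

#: Trailing window (current + previous 4 frames) for label smoothing.
SMOOTHING_WINDOW = 5


# ---------------------------------------------------------------------------
# Gray code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayCode:
    """M x K matrix of +-1 codewords, one column per category.

    Cyclically adjacent columns differ in exactly one row, and all columns
    are distinct.
    """

    code: np.ndarray

    @property
    def K(self) -> int:
        return self.code.shape[1]

    @property
    def M(self) -> int:
        return self.code.shape[0]

    def validate(self) -> None:
        code = self.code
        if not np.all(np.abs(code) == 1):
            raise ValueError("code entries must be +-1")
        for b in range(self.K):
            diff = np.sum(code[:, b] != code[:, (b + 1) % self.K])
            if diff != 1:
                raise ValueError(
                    f"columns {b} and {(b + 1) % self.K} differ in {diff} rows"
                )
        if len({tuple(col) for col in code.T}) != self.K:
            raise ValueError("code columns are not distinct")


def make_gray_code(K: int) -> GrayCode:
    """Cyclic half-window Gray code with M = K/2 output units.

    Row ``m`` is +1 for categories ``b`` with ``(b - m) mod K < K/2``; the
    +1 window of each row is half the cycle, shifted by one category per
    row, which gives the single-bit cyclic adjacency property.
    """
    if K < 2 or K % 2 != 0:
        raise ValueError("K must be even and >= 2")
    M = K // 2
    b = np.arange(K)
    m = np.arange(M)[:, None]
    code = np.where(((b - m) % K) < M, 1, -1).astype(np.int8)
    return GrayCode(code=code)


# ---------------------------------------------------------------------------
# Linear classifier bank
# ---------------------------------------------------------------------------

def _fit_binary(X: np.ndarray, y: np.ndarray, C: float) -> tuple[StandardScaler, LinearSVC]:
    """One standardized L2-regularized linear SVM unit (deterministic
    coordinate-descent solver, no sampling)."""
    scaler = StandardScaler().fit(X)
    clf = LinearSVC(C=C, dual=False, max_iter=5000, random_state=0)
    clf.fit(scaler.transform(X), y)
    return scaler, clf


def _unit_score(unit: tuple[StandardScaler, LinearSVC], X: np.ndarray) -> np.ndarray:
    scaler, clf = unit
    return clf.decision_function(scaler.transform(X))


@dataclass
class DecoderModel:
    """Trained bank of one linear unit per Gray-code row."""

    units: list
    code: GrayCode
    n_inputs: int

    def output_vector(self, X: np.ndarray) -> np.ndarray:
        """Real-valued M-dimensional classifier outputs for frames X
        (shape (n_frames, n_inputs))."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} trace inputs, got {X.shape[1]}"
            )
        return np.column_stack([_unit_score(u, X) for u in self.units])


def train_position_decoder(
    traces: np.ndarray,
    bins: np.ndarray,
    code: GrayCode,
    training_range: slice | tuple[int, int],
    C: float = 1.0,
) -> DecoderModel:
    """Fit the Gray-code classifier bank on the training epoch.

    Parameters
    ----------
    traces:
        Trace matrix of shape (n_traces, n_frames); every trace is used,
        with no spatial-selectivity screening.
    bins:
        Per-frame 1-based position bin in ``1..K``.
    training_range:
        Frames used for fitting.  Every bin must be visited at least once
        within it.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    bins = np.asarray(bins)
    if isinstance(training_range, tuple):
        training_range = slice(*training_range)
    X = traces[:, training_range].T
    y_bins = bins[training_range]
    missing = sorted(set(range(1, code.K + 1)) - set(np.unique(y_bins).tolist()))
    if missing:
        raise ValueError(f"position bins never visited in training: {missing}")
    units = []
    for m in range(code.M):
        targets = code.code[m, y_bins - 1]
        units.append(_fit_binary(X, targets, C))
    return DecoderModel(units=units, code=code, n_inputs=traces.shape[0])


def predict_position(model: DecoderModel, trace_vector: np.ndarray) -> int:
    """Decode one frame: nearest codeword by score-codeword inner product.

    Ties resolve to the lowest bin index.  Returns a 1-based bin.
    """
    return int(predict_position_series(model, np.atleast_2d(trace_vector))[0])


def predict_position_series(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Decode many frames at once; X has shape (n_frames, n_inputs)."""
    scores = model.output_vector(X)  # (n_frames, M)
    sims = scores @ model.code.code.astype(np.float64)  # (n_frames, K)
    return np.argmax(sims, axis=1) + 1  # first max wins -> lowest bin


# ---------------------------------------------------------------------------
# Behavior tree
# ---------------------------------------------------------------------------

@dataclass
class _TreeNode:
    positive: frozenset
    negative: frozenset
    unit: tuple | None  # None -> constant node
    constant: int = 1   # sign emitted when unit is None


@dataclass
class BehaviorTree:
    """Ordered binary tree of linear classifiers over behavior categories.

    Node order (most-frequent-category-first): intertrial vs the rest, then
    pre-trial, then reward retrieval, then correct vs incorrect choice.
    """

    nodes: list
    categories: tuple = BEHAVIOR_CATEGORIES
    smoothing_window: int = SMOOTHING_WINDOW

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = X.shape[0]
        out = np.empty(n, dtype=object)
        undecided = np.ones(n, dtype=bool)
        for node in self.nodes:
            if not undecided.any():
                break
            idx = np.nonzero(undecided)[0]
            if node.unit is None:
                s = np.full(idx.size, float(node.constant))
            else:
                s = _unit_score(node.unit, X[idx])
            pos = s > 0
            if len(node.positive) == 1:
                (pos_label,) = node.positive
                out[idx[pos]] = pos_label
                undecided[idx[pos]] = False
            if len(node.negative) == 1:
                (neg_label,) = node.negative
                out[idx[~pos]] = neg_label
                undecided[idx[~pos]] = False
        if undecided.any():  # pragma: no cover - topology always terminates
            raise RuntimeError("behavior tree left frames unlabelled")
        return out.astype(str)


_DEFAULT_TOPOLOGY = [
    ({"intertrial"}, {"pre-trial", "correct choice", "incorrect choice", "reward retrieval"}),
    ({"pre-trial"}, {"correct choice", "incorrect choice", "reward retrieval"}),
    ({"reward retrieval"}, {"correct choice", "incorrect choice"}),
    ({"correct choice"}, {"incorrect choice"}),
]


def train_behavior_tree(
    predictors: np.ndarray,
    labels: np.ndarray,
    training_range: slice | tuple[int, int],
    C: float = 1.0,
    topology: list | None = None,
) -> BehaviorTree:
    """Fit the binary-tree behavior classifier.

    Parameters
    ----------
    predictors:
        Per-frame feature matrix (n_frames, n_features): calcium trace
        vectors, or the 5-column motion control predictor.
    labels:
        Per-frame category strings from :data:`BEHAVIOR_CATEGORIES`.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=np.float64))
    labels = np.asarray(labels, dtype=str)
    if isinstance(training_range, tuple):
        training_range = slice(*training_range)
    Xtr = X[training_range]
    ytr = labels[training_range]
    present = set(np.unique(ytr).tolist())
    absent = [c for c in BEHAVIOR_CATEGORIES if c not in present]
    if len(present) < 2:
        raise ValueError("need at least two behavior categories in training")
    if absent:
        warnings.warn(f"behavior categories absent from training: {absent}")
    nodes = []
    for pos, neg in (topology or _DEFAULT_TOPOLOGY):
        pos, neg = frozenset(pos), frozenset(neg)
        sel = np.isin(ytr, list(pos | neg))
        targets = np.where(np.isin(ytr[sel], list(pos)), 1, -1)
        classes = np.unique(targets)
        if classes.size < 2:
            const = int(classes[0]) if classes.size else -1
            nodes.append(_TreeNode(pos, neg, None, const))
            continue
        nodes.append(_TreeNode(pos, neg, _fit_binary(Xtr[sel], targets, C)))
    return BehaviorTree(nodes=nodes)


def majority_smooth(raw_labels: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Causal majority vote over the trailing ``window`` frames.

    The window covers the current and previous ``window - 1`` frames
    (shortened at the start of the series).  Ties go to the most recently
    emitted raw label among the tied candidates.
    """
    raw = np.asarray(raw_labels)
    out = np.empty_like(raw)
    for f in range(raw.size):
        win = raw[max(0, f - window + 1) : f + 1]
        values, counts = np.unique(win, return_counts=True)
        best = counts.max()
        tied = set(values[counts == best].tolist())
        # walk backwards to find the most recent raw label among the tied
        for lab in win[::-1]:
            if lab in tied:
                out[f] = lab
                break
    return out


def predict_behavior(tree: BehaviorTree, predictor_series: np.ndarray) -> np.ndarray:
    """Raw per-frame tree labels followed by causal majority smoothing."""
    raw = tree.predict_raw(predictor_series)
    return majority_smooth(raw, tree.smoothing_window)


# ---------------------------------------------------------------------------
# Circular-shift chance control
# ---------------------------------------------------------------------------

def shift_control(
    traces: np.ndarray,
    bins: np.ndarray,
    code: GrayCode,
    training_range: slice | tuple[int, int],
    test_range: slice | tuple[int, int],
    bin_geometry,
    shifts: tuple = DEFAULT_SHIFTS,
    C: float = 1.0,
    tolerance_cm: float = 30.0,
):
    """Chance-level decoding: train on circularly misaligned trace/position
    pairs, test on the correctly aligned pairs.

    For each shift the trace matrix is rolled against the position series
    before training; the trained model is then evaluated on the aligned test
    epoch.  Mean distance error and hit rate are averaged over all shifts.

    Returns
    -------
    dict with per-shift ``lambda_mean`` / ``hit_rate`` lists and their
    averages ``lambda_mean`` and ``hit_rate``.
    """
    from . import metrics as _metrics

    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    bins = np.asarray(bins)
    n_frames = traces.shape[1]
    if max(shifts) >= n_frames:
        raise ValueError(
            f"session of {n_frames} frames shorter than max shift {max(shifts)}"
        )
    if isinstance(test_range, tuple):
        test_range = slice(*test_range)
    lam_means, hit_rates = [], []
    for shift in shifts:
        rolled = np.roll(traces, shift, axis=1)
        model = train_position_decoder(rolled, bins, code, training_range, C=C)
        pred = predict_position_series(model, traces[:, test_range].T)
        lam, lam_bar, rho = _metrics.position_metrics(
            bins[test_range], pred, bin_geometry, tolerance_cm=tolerance_cm
        )
        lam_means.append(lam_bar)
        hit_rates.append(rho)
    return {
        "shifts": list(shifts),
        "lambda_mean_per_shift": lam_means,
        "hit_rate_per_shift": hit_rates,
        "lambda_mean": float(np.mean(lam_means)),
        "hit_rate": float(np.mean(hit_rates)),
    }
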