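"""Evaluation statistics for position and behavior decoding.

* distance error ``lambda(t)`` and hit rate ``rho`` for position decoding
  on the circularized track;
* per-trace spatial tuning curves and the tuning similarity score ``S``;
* the motion-artifact score ``Omega`` correlating decoding error with
  image displacement;
* event-level sensitivity / precision / F-score for behavior decoding,
  with a label-shuffle null distribution.

``S`` and ``Omega`` share the signed log-significance transform
``-log10(P) * sign(R)`` of a Pearson correlation, so a score above 2
corresponds to a positive correlation significant at p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BinGeometry",
    "TuningCurve",
    "EventMetrics",
    "signed_log_significance",
    "position_metrics",
    "tuning_curve",
    "similarity_score",
    "motion_artifact_score",
    "event_metrics",
    "event_displacement_gap",
    "label_runs",
]


@dataclass(frozen=True)
class BinGeometry:
    """Circularized linear-track geometry.

    A track of length ``L_cm`` run in both directions is unrolled onto a
    loop of length ``2 L``, subdivided into ``K`` equal bins (``K/2`` per
    running direction).  Bin ``b`` (1-based) is centered at
    ``(b - 1/2) * 2L / K`` along the loop.
    """

    L_cm: float = 250.0
    K: int = 24

    def __post_init__(self) -> None:
        if self.L_cm <= 0 or self.K < 2 or self.K % 2:
            raise ValueError("need positive track length and even K >= 2")

    @property
    def loop_cm(self) -> float:
        return 2.0 * self.L_cm

    @property
    def bin_width_cm(self) -> float:
        return self.loop_cm / self.K

    def bin_center_cm(self, b) -> np.ndarray:
        return (np.asarray(b) - 0.5) * self.bin_width_cm

    def circular_distance_cm(self, b1, b2) -> np.ndarray:
        """Distance between bin centers along the loop (shorter way round)."""
        diff = np.abs(self.bin_center_cm(b1) - self.bin_center_cm(b2))
        return np.minimum(diff, self.loop_cm - diff)


def signed_log_significance(R: float, P: float) -> float:
    """``-log10(P) * sign(R)``: magnitude is the log significance of the
    correlation, sign follows the correlation's direction.

    A p-value that underflows to zero is clamped to the smallest positive
    double so the score stays finite.
    """
    if not np.isfinite(R) or not np.isfinite(P):
        return float("nan")
    return float(-np.log10(max(P, 1e-300)) * np.sign(R))


def position_metrics(
    true_bins: np.ndarray,
    predicted_bins: np.ndarray,
    geometry: BinGeometry,
    tolerance_cm: float = 30.0,
) -> tuple[np.ndarray, float, float]:
    """Per-frame distance error, its mean, and the hit rate.

    ``lambda(t)`` is the circular distance (cm) along the circularized
    track between the true and decoded bin centers; the hit rate ``rho``
    is the percentage of frames with ``lambda <= tolerance_cm``.
    """
    true_bins = np.asarray(true_bins)
    predicted_bins = np.asarray(predicted_bins)
    if true_bins.shape != predicted_bins.shape:
        raise ValueError("true and predicted series must have equal length")
    lam = geometry.circular_distance_cm(true_bins, predicted_bins)
    lam_bar = float(lam.mean())
    rho = float(100.0 * np.mean(lam <= tolerance_cm))
    return lam, lam_bar, rho


@dataclass(frozen=True)
class TuningCurve:
    """Mean zero-referenced activity per position bin.

    ``A`` is the raw per-bin average of ``Z(f) = T(f) - min(T)``;
    ``normalized`` divides by the maximum element.  ``visits`` counts
    frames per bin; unvisited bins carry ``A = nan`` and are flagged, as is
    an all-zero curve (``degenerate``).
    """

    A: np.ndarray
    normalized: np.ndarray
    visits: np.ndarray
    degenerate: bool


def tuning_curve(trace: np.ndarray, bins: np.ndarray, K: int = 24) -> TuningCurve:
    """Spatial tuning curve of one trace over K position bins."""
    T = np.asarray(trace, dtype=np.float64)
    bins = np.asarray(bins)
    if T.shape != bins.shape:
        raise ValueError("trace and bin series must have equal length")
    Z = T - T.min()
    A = np.full(K, np.nan)
    visits = np.zeros(K, dtype=int)
    for b in range(1, K + 1):
        sel = bins == b
        visits[b - 1] = np.count_nonzero(sel)
        if visits[b - 1]:
            A[b - 1] = Z[sel].mean()
    peak = np.nanmax(A) if np.any(visits > 0) else np.nan
    if not np.isfinite(peak) or peak == 0:
        return TuningCurve(A=A, normalized=np.zeros(K), visits=visits, degenerate=True)
    return TuningCurve(A=A, normalized=A / peak, visits=visits, degenerate=False)


def similarity_score(curve_train: np.ndarray, curve_test: np.ndarray) -> float:
    """Tuning similarity ``S = -log10(P) * sign(R)`` between two epochs.

    ``R, P`` are the Pearson correlation and its two-sided p-value between
    the train- and test-epoch tuning curves (valid bins only).  Returns nan
    when fewer than 3 bins are valid in both curves or either curve has
    zero variance.
    """
    a = np.asarray(curve_train, dtype=np.float64)
    b = np.asarray(curve_test, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("curves must have the same bin count")
    valid = np.isfinite(a) & np.isfinite(b)
    if np.count_nonzero(valid) < 3:
        return float("nan")
    a, b = a[valid], b[valid]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    res = stats.pearsonr(a, b)
    return signed_log_significance(res.statistic, res.pvalue)


def motion_artifact_score(
    lam: np.ndarray,
    d: np.ndarray,
    bins: np.ndarray,
    pixel_threshold: float = 4.0,
) -> float:
    """Signed log-significance of the correlation between decoding error
    and image displacement.

    Only frames from position bins in which the maximum displacement ``d``
    exceeds ``pixel_threshold`` enter the correlation — elsewhere motion
    artifact could not have influenced the traces, so those frames only
    dilute the test.  Returns nan when no bin qualifies or the correlation
    is undefined.
    """
    lam = np.asarray(lam, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    bins = np.asarray(bins)
    if not (lam.shape == d.shape == bins.shape):
        raise ValueError("lambda, displacement, and bin series must align")
    qualifying = [b for b in np.unique(bins) if d[bins == b].max() > pixel_threshold]
    if not qualifying:
        return float("nan")
    sel = np.isin(bins, qualifying)
    if np.count_nonzero(sel) < 3 or lam[sel].std() == 0 or d[sel].std() == 0:
        return float("nan")
    res = stats.pearsonr(lam[sel], d[sel])
    return signed_log_significance(res.statistic, res.pvalue)


# ---------------------------------------------------------------------------
# Event-level behavior metrics
# ---------------------------------------------------------------------------

def label_runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Contiguous runs of a label series as ``(label, start, stop)`` with
    ``stop`` exclusive."""
    labels = np.asarray(labels)
    runs = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append((str(labels[start]), start, i))
            start = i
    return runs


@dataclass(frozen=True)
class EventMetrics:
    """Event-level classification metrics (percent) with a shuffle null."""

    sensitivity: float
    precision: float
    f_score: float
    frame_sensitivity: float
    frame_precision: float
    n_events: int
    null_f: np.ndarray
    p_value: float


def _event_scores(
    true_labels: np.ndarray, predicted_labels: np.ndarray, event_type: str
) -> tuple[float, float, float]:
    true_runs = [r for r in label_runs(true_labels) if r[0] == event_type]
    if not true_runs:
        return float("nan"), float("nan"), float("nan")
    pred_is_event = np.asarray(predicted_labels) == event_type
    true_is_event = np.asarray(true_labels) == event_type
    # an event is correctly predicted if any frame inside its window is
    # labelled with the event
    hits = sum(1 for _, s, e in true_runs if pred_is_event[s:e].any())
    sensitivity = 100.0 * hits / len(true_runs)
    pred_runs = [r for r in label_runs(predicted_labels) if r[0] == event_type]
    if pred_runs:
        correct = sum(1 for _, s, e in pred_runs if true_is_event[s:e].any())
        precision = 100.0 * correct / len(pred_runs)
    else:
        precision = 0.0
    if sensitivity == 0 or (precision + sensitivity) == 0:
        f = 0.0
    else:
        f = 2.0 * precision * sensitivity / (precision + sensitivity)
    return sensitivity, precision, f


def event_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    event_type: str,
    n_shuffles: int = 1000,
    seed: int | None = 0,
) -> EventMetrics:
    """Sensitivity, precision, and F-score for one behavior event type.

    An event (contiguous window of ``event_type`` in the true labels) counts
    as correctly predicted when at least one frame inside its window carries
    the predicted event label; precision is the fraction of predicted event
    windows that overlap a true one; ``F = 2PS / (P + S)``.  Frame-level
    sensitivity/precision are reported alongside for transparency.

    The null distribution permutes the labels of the true label windows
    among the windows (window boundaries fixed) ``n_shuffles`` times and
    recomputes F against the same predictions; the p-value is the fraction
    of null F values >= the actual F.
    """
    true_labels = np.asarray(true_labels, dtype=str)
    predicted_labels = np.asarray(predicted_labels, dtype=str)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label series must have equal length")
    runs = label_runs(true_labels)
    n_events = sum(1 for r in runs if r[0] == event_type)
    if n_events == 0:
        warnings.warn(f"no '{event_type}' events in the true labels")
        return EventMetrics(
            *(float("nan"),) * 5, 0, np.array([]), float("nan")
        )
    sens, prec, f = _event_scores(true_labels, predicted_labels, event_type)
    true_frames = true_labels == event_type
    pred_frames = predicted_labels == event_type
    tp = np.count_nonzero(true_frames & pred_frames)
    frame_sens = 100.0 * tp / true_frames.sum()
    frame_prec = 100.0 * tp / pred_frames.sum() if pred_frames.any() else 0.0

    rng = np.random.default_rng(seed)
    run_labels = np.array([r[0] for r in runs])
    null = np.empty(n_shuffles)
    shuffled = np.empty_like(true_labels)
    for k in range(n_shuffles):
        perm = rng.permutation(run_labels)
        for lab, (_, s, e) in zip(perm, runs):
            shuffled[s:e] = lab
        null[k] = _event_scores(shuffled, predicted_labels, event_type)[2]
    finite_null = null[np.isfinite(null)]
    if finite_null.size:
        p_value = float(np.mean(finite_null >= f)) if np.isfinite(f) else float("nan")
    else:
        p_value = float("nan")
    return EventMetrics(
        sensitivity=sens,
        precision=prec,
        f_score=f,
        frame_sensitivity=frame_sens,
        frame_precision=frame_prec,
        n_events=n_events,
        null_f=null,
        p_value=p_value,
    )


def event_displacement_gap(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    d: np.ndarray,
    event_type: str,
) -> dict:
    """Image displacement during correctly vs incorrectly classified event
    frames.

    Isolates the frames whose true label is ``event_type`` and splits them
    into 'predicted' (decoder emitted the event label on that frame) and
    'unpredicted'.  A decoder that keys on motion artifact rather than
    neural signal preferentially recognizes the event frames accompanied by
    image motion, so the median displacement of predicted frames exceeds
    that of unpredicted frames; after motion correction the two should be
    at parity.  Significance is a one-sided rank-sum (Mann-Whitney) test of
    predicted > unpredicted.

    Returns a dict with ``median_predicted``, ``median_unpredicted``,
    ``gap`` (0 when either side is empty — no motion-selective prediction
    can be demonstrated), ``p_value``, and the two frame counts.
    """
    true_labels = np.asarray(true_labels, dtype=str)
    predicted_labels = np.asarray(predicted_labels, dtype=str)
    d = np.asarray(d, dtype=np.float64)
    in_event = true_labels == event_type
    hit = in_event & (predicted_labels == event_type)
    miss = in_event & (predicted_labels != event_type)
    d_pred, d_unpred = d[hit], d[miss]
    med_p = float(np.median(d_pred)) if d_pred.size else float("nan")
    med_u = float(np.median(d_unpred)) if d_unpred.size else float("nan")
    if d_pred.size and d_unpred.size:
        gap = med_p - med_u
        p_value = float(
            stats.mannwhitneyu(d_pred, d_unpred, alternative="greater").pvalue
        )
    else:
        gap, p_value = 0.0, float("nan")
    return {
        "median_predicted": med_p,
        "median_unpredicted": med_u,
        "gap": gap,
        "p_value": p_value,
        "n_predicted_frames": int(d_pred.size),
        "n_unpredicted_frames": int(d_unpred.size),
    }
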