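"""Evaluation statistics: distance error, tuning curves, score transform,
motion-artifact score, and event metrics with shuffle nulls."""

import numpy as np
import pytest
from scipy import stats

from calcistream.metrics import (
    BinGeometry,
    event_displacement_gap,
    event_metrics,
    label_runs,
    motion_artifact_score,
    position_metrics,
    signed_log_significance,
    similarity_score,
    tuning_curve,
)

GEOM = BinGeometry(L_cm=250.0, K=24)


class TestPositionMetrics:
    def test_perfect_prediction(self):
        bins = np.array([1, 5, 12, 24])
        lam, lam_bar, rho = position_metrics(bins, bins, GEOM)
        assert lam_bar == 0.0 and rho == 100.0

    def test_diametric_prediction_is_half_loop(self):
        true = np.array([1, 2, 3])
        pred = (true + 12 - 1) % 24 + 1  # 12 bins away on the 24-bin loop
        lam, lam_bar, rho = position_metrics(true, pred, GEOM)
        assert np.allclose(lam, 250.0)  # half of the 500-cm circularized loop
        assert rho == 0.0

    def test_matches_enumeration_oracle(self, rng):
        true = rng.integers(1, 25, size=10)
        pred = rng.integers(1, 25, size=10)
        lam, lam_bar, rho = position_metrics(true, pred, GEOM)
        width = 500.0 / 24
        for t, p, l in zip(true, pred, lam):
            steps = min(abs(t - p), 24 - abs(t - p))
            assert l == pytest.approx(steps * width)
        assert lam_bar == pytest.approx(lam.mean())
        assert rho == pytest.approx(100.0 * np.mean(lam <= 30.0))

    def test_hit_rate_monotone_in_tolerance(self, rng):
        true = rng.integers(1, 25, size=200)
        pred = rng.integers(1, 25, size=200)
        rhos = [
            position_metrics(true, pred, GEOM, tolerance_cm=tol)[2]
            for tol in (10.0, 30.0, 60.0, 120.0)
        ]
        assert rhos == sorted(rhos)


class TestTuningCurve:
    def test_activity_in_single_bin_gives_one_hot_curve(self):
        bins = np.array([5, 5, 7, 7, 9])
        trace = np.array([10.0, 12.0, 0.0, 0.0, 0.0])
        tc = tuning_curve(trace, bins)
        assert tc.normalized[4] == 1.0  # bin 5
        assert tc.visits[4] == 2
        assert not tc.degenerate

    def test_constant_trace_flagged_degenerate(self):
        tc = tuning_curve(np.full(10, 4.0), np.arange(1, 11))
        assert tc.degenerate
        assert np.all(tc.normalized == 0)

    def test_matches_double_loop_binning_oracle(self, rng):
        trace = rng.random(300) * 100
        bins = rng.integers(1, 25, size=300)
        tc = tuning_curve(trace, bins)
        Z = trace - trace.min()
        for b in range(1, 25):
            frames = [i for i in range(300) if bins[i] == b]
            if frames:
                assert tc.A[b - 1] == pytest.approx(np.mean([Z[i] for i in frames]))

    def test_unvisited_bins_flagged_nan(self):
        tc = tuning_curve(np.arange(5.0), np.array([1, 1, 2, 2, 3]))
        assert np.isnan(tc.A[5])
        assert tc.visits[5] == 0


class TestScoreTransform:
    @pytest.mark.parametrize("P,expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_closed_form_values(self, P, expected):
        assert signed_log_significance(0.5, P) == pytest.approx(expected)
        assert signed_log_significance(-0.5, P) == pytest.approx(-expected)

    def test_identical_curves_score_large_positive(self, rng):
        curve = rng.random(24)
        s = similarity_score(curve, curve + rng.normal(0, 1e-6, 24))
        assert s > 2.0

    def test_zero_variance_curve_reported_missing(self):
        assert np.isnan(similarity_score(np.ones(24), np.arange(24.0)))

    def test_too_few_valid_bins_missing(self):
        a = np.array([1.0, 2.0, np.nan] + [np.nan] * 21)
        b = np.array([2.0, 1.0, np.nan] + [np.nan] * 21)
        assert np.isnan(similarity_score(a, b))

    def test_false_positive_rate_near_nominal(self, rng):
        """Independent random curves exceed |S| = 2 in about 1% of draws."""
        hits = 0
        n = 3000
        for _ in range(n):
            s = similarity_score(rng.random(24), rng.random(24))
            if abs(s) > 2.0:
                hits += 1
        assert 0.002 < hits / n < 0.025


class TestMotionArtifactScore:
    def test_constructed_correlation_is_significant(self, rng):
        bins = rng.integers(1, 25, size=400)
        d = rng.random(400) * 10
        lam = 5.0 * d + rng.normal(0, 1.0, 400)
        omega = motion_artifact_score(lam, d, bins)
        assert omega > 2.0

    def test_all_displacements_below_threshold_missing(self, rng):
        bins = rng.integers(1, 25, size=100)
        d = np.full(100, 2.0)  # never exceeds the 4-pixel threshold
        lam = rng.random(100)
        assert np.isnan(motion_artifact_score(lam, d, bins))

    def test_only_qualifying_bins_enter_the_correlation(self, rng):
        # bin 1 has large displacement; bin 2 does not
        bins = np.array([1] * 50 + [2] * 50)
        d = np.concatenate([rng.random(50) * 10, np.zeros(50)])
        lam_in_bin1 = 3.0 * d[:50] + rng.normal(0, 0.5, 50)
        lam = np.concatenate([lam_in_bin1, rng.random(50) * 100])
        omega_all = motion_artifact_score(lam, d, bins)
        r, p = stats.pearsonr(lam_in_bin1, d[:50])
        assert omega_all == pytest.approx(-np.log10(p) * np.sign(r))

    def test_null_rate_calibrated(self, rng):
        """With d independent of the error, |Omega| > 2 is rare."""
        n_sig = 0
        n_sessions = 300
        for _ in range(n_sessions):
            bins = rng.integers(1, 5, size=150)
            d = rng.random(150) * 10
            lam = rng.random(150) * 100
            if abs(motion_artifact_score(lam, d, bins)) > 2.0:
                n_sig += 1
        assert n_sig / n_sessions < 0.05


class TestEventMetrics:
    def test_perfect_prediction_scores_100(self):
        labels = np.array(["a"] * 5 + ["ev"] * 5 + ["a"] * 5)
        m = event_metrics(labels, labels, "ev", n_shuffles=50, seed=0)
        assert m.sensitivity == m.precision == m.f_score == 100.0

    def test_f_equals_p_when_sensitivity_equals_precision(self):
        # 2pp/(p+p) = p
        labels = np.array(
            ["x"] * 4 + ["ev"] * 3 + ["x"] * 4 + ["ev"] * 3 + ["x"] * 4
        )
        pred = np.array(
            ["x"] * 4 + ["ev"] * 3 + ["x"] * 4 + ["x"] * 3 + ["ev"] * 2 + ["x"] * 2
        )
        m = event_metrics(labels, pred, "ev", n_shuffles=50, seed=0)
        assert m.sensitivity == m.precision == 50.0
        assert m.f_score == 50.0

    def test_hand_counted_20_frame_session(self):
        truth = np.array(
            ["i", "i", "ev", "ev", "ev", "i", "i", "ev", "ev", "i",
             "i", "ev", "ev", "ev", "i", "i", "i", "i", "ev", "ev"]
        )
        pred = np.array(
            ["i", "i", "ev", "i", "i", "i", "i", "i", "i", "i",
             "ev", "ev", "i", "i", "i", "i", "ev", "i", "i", "i"]
        )
        # 4 true events at frames 2-4, 7-8, 11-13, 18-19; windows 1 and 3
        # contain a predicted frame -> sensitivity 50%.  3 predicted runs
        # (frame 2; frames 10-11; frame 16): runs 1 and 2 overlap true
        # events -> precision 2/3.
        m = event_metrics(truth, pred, "ev", n_shuffles=50, seed=0)
        assert m.n_events == 4
        assert m.sensitivity == pytest.approx(50.0)
        assert m.precision == pytest.approx(100 * 2 / 3)
        expected_f = 2 * 50 * (200 / 3) / (50 + 200 / 3)
        assert m.f_score == pytest.approx(expected_f)

    def test_zero_events_reported_missing(self):
        labels = np.array(["a"] * 10)
        with pytest.warns(UserWarning, match="no 'ev' events"):
            m = event_metrics(labels, labels, "ev", n_shuffles=10, seed=0)
        assert np.isnan(m.f_score)

    def test_shuffled_predictions_fall_inside_null(self, rng):
        """A prediction with no real association scores a large p-value."""
        labels = np.array((["i"] * 6 + ["ev"] * 3) * 12)
        pred = labels.copy()
        rng.shuffle(pred)
        m = event_metrics(labels, pred, "ev", n_shuffles=300, seed=1)
        assert m.p_value > 0.05


def test_label_runs_partition():
    labels = np.array(["a", "a", "b", "c", "c", "c"])
    runs = label_runs(labels)
    assert runs == [("a", 0, 2), ("b", 2, 3), ("c", 3, 6)]


def test_displacement_gap_detects_motion_selective_prediction():
    # two events: one with motion (predicted), one without (missed)
    truth = np.array(["i"] * 3 + ["ev"] * 4 + ["i"] * 3 + ["ev"] * 4 + ["i"] * 3)
    pred = np.array(["i"] * 3 + ["ev"] * 4 + ["i"] * 3 + ["i"] * 4 + ["i"] * 3)
    d = np.zeros(17)
    d[3:7] = 5.0
    g = event_displacement_gap(truth, pred, d, "ev")
    assert g["median_predicted"] == 5.0
    assert g["median_unpredicted"] == 0.0
    assert g["gap"] == 5.0
    # no predicted frames at all -> gap defined as 0
    g2 = event_displacement_gap(truth, np.array(["i"] * 17), d, "ev")
    assert g2["gap"] == 0.0 and np.isnan(g2["median_predicted"])
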