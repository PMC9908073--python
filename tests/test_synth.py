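"""Synthetic-session generator: trajectory geometry, place-cell rendering,
motion scripting, behavior labels, and determinism."""

import numpy as np
import pytest

from calcistream.synth import (
    BackgroundSpec,
    BehaviorTiming,
    FieldSpec,
    GroundTruthCell,
    MotionEvent,
    MotionScript,
    NoiseParams,
    Trajectory,
    compute_true_traces,
    generate_behavior_session,
    generate_place_cell_population,
    generate_trajectory,
    position_bin_index,
    render_session,
)
from calcistream.decode import BEHAVIOR_CATEGORIES
from calcistream.traces import make_tile_masks


class TestTrajectory:
    def test_constant_speed_run_takes_distance_over_speed_frames(self):
        # 250 cm at 50 cm/s and 20 fps -> 100 frames per full run
        traj = generate_trajectory(
            L_cm=250, n_frames=250, fps=20, speed_cm_s=50, dwell_s=0.0, seed=0
        )
        assert traj.position_cm[0] == 0.0
        assert traj.position_cm[100] == pytest.approx(250.0)

    def test_bin_width_about_20cm(self):
        # 24 bins on the 2 x 250 cm circularized path
        traj = generate_trajectory(n_frames=2000, seed=0)
        width = 2 * 250.0 / 24
        assert width == pytest.approx(20.83, abs=0.01)
        # brute-force from bin edges: every frame's circularized coordinate
        # falls inside its bin's span
        half = 12
        for f in range(0, 2000, 37):
            circ = (
                traj.position_cm[f]
                if traj.direction[f] == "rightward"
                else 2 * 250.0 - traj.position_cm[f]
            )
            b = traj.bin_index[f]
            lo, hi = (b - 1) * width, b * width
            assert lo - 1e-9 <= min(circ, 2 * 250.0 - 1e-9) <= hi + width  # clamped ends

    def test_bins_split_by_direction(self):
        traj = generate_trajectory(n_frames=3000, seed=1)
        right = traj.bin_index[traj.direction == "rightward"]
        left = traj.bin_index[traj.direction == "leftward"]
        assert right.max() <= 12 and left.min() >= 13

    def test_same_seed_reproduces_positions(self):
        a = generate_trajectory(n_frames=500, speed_jitter=0.2, seed=7)
        b = generate_trajectory(n_frames=500, speed_jitter=0.2, seed=7)
        assert np.array_equal(a.position_cm, b.position_cm)

    def test_speed_limited_per_frame(self):
        traj = generate_trajectory(n_frames=2000, speed_cm_s=140, speed_jitter=0.5, seed=2)
        steps = np.abs(np.diff(traj.position_cm))
        assert np.all(steps <= 150.0 / 20.0 + 1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"L_cm": -1}, {"n_frames": 0}, {"fps": 0}, {"speed_cm_s": 0},
    ])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_trajectory(**kwargs)


class TestPlaceCells:
    def test_single_cell_peaks_in_its_central_bin(self):
        template = generate_place_cell_population(1, seed=0)[0]
        traj = generate_trajectory(n_frames=2000, seed=0)
        cell = GroundTruthCell(
            footprint=template.footprint,
            origin=template.origin,
            field_center_cm=125.0,
            field_width_cm=template.field_width_cm,
            direction_pref="rightward",
            amplitude=60.0,
        )
        traces = compute_true_traces([cell], traj)
        bins = traj.bin_index
        per_bin = [traces[0, bins == b].mean() if (bins == b).any() else 0 for b in range(1, 25)]
        # 125 cm rightward sits in bin 7 of 12 (bin width ~20.8 cm)
        assert int(np.argmax(per_bin)) + 1 == position_bin_index(
            np.array([125.0]), np.array(["rightward"])
        )[0]

    def test_fifty_uniform_centers_have_ordered_peaks(self):
        traj = generate_trajectory(n_frames=4000, seed=3)
        cells = generate_place_cell_population(50, seed=3)
        traces = compute_true_traces(cells, traj)
        right = [c for c in cells if c.direction_pref == "rightward"]
        idx = [i for i, c in enumerate(cells) if c.direction_pref == "rightward"]
        peaks = []
        for i in idx:
            sel = traj.direction == "rightward"
            pos = traj.position_cm[sel]
            peaks.append(pos[np.argmax(traces[i, sel])])
        centers = [c.field_center_cm for c in right]
        assert np.corrcoef(centers, peaks)[0, 1] > 0.95

    def test_zero_amplitude_cell_contributes_nothing(self):
        traj = generate_trajectory(n_frames=300, seed=0)
        cells = generate_place_cell_population(1, FieldSpec(amplitude=0.0), seed=0)
        assert compute_true_traces(cells, traj).max() == 0.0

    def test_out_of_bounds_footprint_rejected(self):
        with pytest.raises(ValueError, match="exceeds frame bounds"):
            generate_place_cell_population(
                4, FieldSpec(margin_px=2, radius_px=6, center_jitter_px=0.0), seed=0
            )


def test_impulse_activation_halves_after_fourteen_frames():
    """Half-decay 0.7 s at 20 fps -> activation falls to 50% 14 frames
    after a single-frame impulse."""
    n = 30
    traj = Trajectory(
        position_cm=np.concatenate([[125.0], np.zeros(n - 1)]),
        direction=np.array(["rightward"] * n),
        fps=20.0,
    )
    cell = GroundTruthCell(
        footprint=np.ones((3, 3)),
        origin=(10, 10),
        field_center_cm=125.0,
        field_width_cm=1.0,
        direction_pref="rightward",
        amplitude=100.0,
        decay_halftime_s=0.7,
    )
    traces = compute_true_traces([cell], traj)
    assert traces[0, 0] == pytest.approx(100.0)
    assert traces[0, 14] == pytest.approx(50.0, rel=1e-9)


class TestMotionScript:
    def test_jitter_returns_shift_persists(self):
        script = MotionScript.from_events(
            10, [MotionEvent("jitter", 2, 3, 0, duration=2), MotionEvent("shift", 6, 0, -2)]
        )
        assert script.dx.tolist() == [0, 0, 3, 3, 0, 0, 0, 0, 0, 0]
        assert script.dy.tolist() == [0, 0, 0, 0, 0, 0, -2, -2, -2, -2]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            MotionEvent("wobble", 0, 1, 1)


class TestRendering:
    def test_static_scene_renders_identical_frames(self):
        traj = generate_trajectory(n_frames=5, seed=0)
        sess = render_session(
            [], traj, noise_params=NoiseParams(sigma=0.0),
            background=BackgroundSpec(texture_amp=0.0), seed=0,
            frame_shape=(64, 64),
        )
        for f in range(1, 5):
            assert np.array_equal(sess.frames[f], sess.frames[0])

    def test_jittered_frames_equal_translated_base(self):
        from calcistream.stabilize import translate

        traj = generate_trajectory(n_frames=6, seed=0)
        motion = MotionScript.from_events(6, [MotionEvent("jitter", 3, 3, 0, duration=2)])
        sess = render_session(
            [], traj, motion=motion, noise_params=NoiseParams(sigma=0.0), seed=0,
            frame_shape=(64, 64),
        )
        assert np.array_equal(sess.frames[3], translate(sess.frames[0], 3, 0))
        assert np.array_equal(sess.frames[5], sess.frames[0])

    def test_same_seed_bit_identical(self):
        traj = generate_trajectory(n_frames=20, seed=4)
        cells = generate_place_cell_population(5, seed=4, frame_shape=(128, 128))
        a = render_session(cells, traj, seed=4, frame_shape=(128, 128))
        b = render_session(cells, traj, seed=4, frame_shape=(128, 128))
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.true_traces, b.true_traces)

    def test_noiseless_tile_sums_track_ground_truth(self, small_track_session):
        """Summing rendered pixels over a cell's footprint recovers its
        true trace (up to uint8 quantization and the static background)."""
        sess = small_track_session
        still = np.nonzero(sess.motion.d() == 0)[0]
        cell = sess.cells[0]
        r0, c0 = cell.origin
        h, w = cell.footprint.shape
        base = sess.frames[still[0]][r0 : r0 + h, c0 : c0 + w].astype(float)
        fp_sum = cell.footprint.sum()
        for f in still[:: max(len(still) // 20, 1)]:
            patch = sess.frames[f][r0 : r0 + h, c0 : c0 + w].astype(float)
            est = (patch - base).sum() / fp_sum + sess.true_traces[0, still[0]]
            assert est == pytest.approx(sess.true_traces[0, f], abs=2.0)

    def test_saturation_warns(self):
        traj = generate_trajectory(n_frames=5, seed=0)
        with pytest.warns(UserWarning, match="saturation"):
            render_session(
                [], traj, background=BackgroundSpec(offset=260.0), seed=0,
                frame_shape=(32, 32), noise_params=NoiseParams(sigma=0.0),
            )


class TestBehaviorSession:
    def test_labels_partition_every_frame(self):
        sess = generate_behavior_session(5, seed=0, render_frames=False)
        assert sess.behavior_labels.shape == (sess.n_frames,)
        assert set(sess.behavior_labels.tolist()) <= set(BEHAVIOR_CATEGORIES)

    def test_reward_window_is_two_seconds_of_frames(self):
        sess = generate_behavior_session(
            3, BehaviorTiming(p_correct=1.0), seed=0, render_frames=False
        )
        from calcistream.metrics import label_runs

        rewards = [r for r in label_runs(sess.behavior_labels) if r[0] == "reward retrieval"]
        assert len(rewards) == 3
        assert all(e - s == 40 for _, s, e in rewards)  # 2 s x 20 fps

    def test_single_all_correct_trial(self):
        sess = generate_behavior_session(
            1, BehaviorTiming(p_correct=1.0), seed=0, render_frames=False
        )
        from calcistream.metrics import label_runs

        runs = label_runs(sess.behavior_labels)
        assert sum(1 for r in runs if r[0] == "correct choice") == 1
        assert sum(1 for r in runs if r[0] == "incorrect choice") == 0

    def test_behavior_locked_jitter_elevates_reward_motion(self):
        sess = generate_behavior_session(
            12, BehaviorTiming(p_correct=1.0, jitter_prob=1.0), seed=1,
            render_frames=False,
        )
        add = sess.motion.abs_delta_d()
        labels = sess.behavior_labels
        assert add[labels == "reward retrieval"].mean() > add[labels == "intertrial"].mean()

    def test_determinism(self):
        a = generate_behavior_session(4, seed=9, render_frames=False)
        b = generate_behavior_session(4, seed=9, render_frames=False)
        assert np.array_equal(a.behavior_labels, b.behavior_labels)
        assert np.array_equal(a.true_traces, b.true_traces)
        assert np.array_equal(a.motion.dx, b.motion.dx)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior_session(0, seed=0)
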