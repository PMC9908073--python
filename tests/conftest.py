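import numpy as np
import pytest

from calcistream.synth import (
    FieldSpec,
    MotionEvent,
    MotionScript,
    NoiseParams,
    generate_place_cell_population,
    generate_trajectory,
    render_session,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_track_session():
    """A short rendered linear-track session with scripted motion.

    300 frames, 30 cells, noiseless rendering, one transient jitter and one
    persistent shift — small enough to run the full pipeline in seconds
    while exercising every stage.
    """
    traj = generate_trajectory(n_frames=300, fps=20.0, seed=11)
    cells = generate_place_cell_population(30, FieldSpec(), seed=11)
    motion = MotionScript.from_events(
        300,
        [
            MotionEvent("jitter", 120, 3, -2, 4),
            MotionEvent("shift", 200, -5, 4),
        ],
    )
    return render_session(
        cells, traj, motion=motion, noise_params=NoiseParams(sigma=0.0), seed=11
    )
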