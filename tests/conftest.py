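import numpy as np
import pytest

from swaybalance import (
    MotionConfig,
    RenderParams,
    SwayModelParams,
    Trajectory,
    render_silhouette_video,
    simulate_sway_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def random_trajectory(rng):
    """A generic finite random-walk trajectory at 30 Hz."""
    return Trajectory(
        x=np.cumsum(rng.normal(0, 1, 200)),
        y=np.cumsum(rng.normal(0, 1, 200)),
        rate_hz=30.0,
        units="pixel",
    )


@pytest.fixture(scope="session")
def sway_trajectory():
    """A 30 s band-limited sway trajectory at 30 Hz with sway SD 8 px."""
    return simulate_sway_trajectory(SwayModelParams(
        amplitude_x=8.0, amplitude_y=5.0, bandwidth_hz=1.0,
        duration_s=30.0, rate_hz=30.0, seed=11,
    ))


@pytest.fixture(scope="session")
def rendered_sway(sway_trajectory):
    """The sway trajectory rendered as a textured silhouette video."""
    render = RenderParams(frame_width=128, frame_height=160)
    return render_silhouette_video(sway_trajectory, render), sway_trajectory


@pytest.fixture
def motion_config():
    return MotionConfig()
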