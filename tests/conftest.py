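import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import larvatrack as lt
from larvatrack.pose import N_POINTS, PoseSeries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def straight_series(
    n_frames: int = 40,
    length: float = 4.2,
    speed: float = 0.0,
    frame_rate: float = 7.5,
    origin=(0.0, 0.0),
) -> PoseSeries:
    """A rigid straight worm moving head-first along +x at constant speed."""
    times = np.arange(n_frames) / frame_rate
    base = np.zeros((N_POINTS, 2))
    base[:, 0] = np.linspace(0.0, -length, N_POINTS)  # head at x=0, tail behind
    pts = base[None, :, :] + np.zeros((n_frames, 1, 2))
    pts[:, :, 0] += origin[0] + speed * times[:, None]
    pts[:, :, 1] += origin[1]
    return PoseSeries(
        times=times,
        points=pts,
        valid=np.ones(n_frames, dtype=bool),
        frame_rate=frame_rate,
    )


@pytest.fixture(scope="session")
def sim_session():
    """A 60 s default-configuration crawl with ground truth."""
    cfg = lt.SimConfig(duration=60.0, rng_seed=3)
    series, truth = lt.simulate_crawl(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def rendered_session(sim_session):
    """The same crawl rendered to frames and recognized back."""
    cfg, series, truth = sim_session
    frames, stage = lt.render_frames(series)
    recognized = lt.recognize_video(
        frames, stage, lt.CalibrationInfo(0.045), frame_rate=cfg.frame_rate
    )
    return cfg, truth, frames, stage, recognized
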