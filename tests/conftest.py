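import numpy as np
import pytest

from gaitkit.events import detect_events
from gaitkit.parameters import build_strides, summarize
from gaitkit.simulate import GaitSimConfig, simulate
from gaitkit.skeleton import DEFAULT_SKELETON
from gaitkit.trajectories import Trajectory, preprocess


def run_pipeline(cfg: GaitSimConfig) -> dict:
    """Simulate one bout and run the full analysis chain on it."""
    traj, gt = simulate(cfg)
    pp = preprocess(traj)
    events = detect_events(pp)
    strides = build_strides(events, pp)
    return {
        "cfg": cfg, "traj": traj, "gt": gt, "pp": pp,
        "events": events, "strides": strides,
        "summary": summarize(strides),
    }


@pytest.fixture(scope="session")
def noiseless_bout() -> dict:
    """100 recorded gait cycles at 1.2 m/s, 1.1 s stride time, 30 Hz."""
    return run_pipeline(GaitSimConfig(n_strides=50, seed=3))


@pytest.fixture(scope="session")
def noisy_bout() -> dict:
    """Same bout with 5 mm isotropic keypoint noise."""
    return run_pipeline(GaitSimConfig(n_strides=50, noise_std=0.005, seed=3))


@pytest.fixture(scope="session")
def small_bout() -> dict:
    """Short noiseless bout for cheap structural checks."""
    return run_pipeline(GaitSimConfig(n_strides=12, seed=7))


def single_keypoint_traj(t: np.ndarray, xyz: np.ndarray, rate: float,
                         keypoint: str = "head",
                         mask: np.ndarray | None = None) -> Trajectory:
    """Trajectory with one keypoint of interest; the rest sit at origin."""
    n = t.size
    k = len(DEFAULT_SKELETON.keypoint_names)
    pos = np.zeros((n, k, 3))
    pos[:, DEFAULT_SKELETON.index(keypoint), :] = xyz
    m = np.ones((n, k), dtype=bool)
    if mask is not None:
        m[:, DEFAULT_SKELETON.index(keypoint)] = mask
    return Trajectory(t, pos, m, rate)
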