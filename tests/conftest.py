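import numpy as np
import pytest

from headmotion.synth import TrajectoryModel, simulate_head_trajectory


@pytest.fixture(scope="session")
def foraging_trajectory():
    """One 300-s unconstrained foraging trajectory with its event log."""
    return simulate_head_trajectory(TrajectoryModel(duration=300.0, seed=11))


@pytest.fixture(scope="session")
def foraging_trial_pair():
    """Two independent 300-s trials, standing in for the two light trials."""
    return [
        simulate_head_trajectory(TrajectoryModel(duration=300.0, seed=s))
        for s in (41, 42)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def geodesic_error_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Rotation angle (deg) between two rotation matrices."""
    cosang = (np.trace(R1 @ R2.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def wrap_deg(x):
    """Wrap angle differences onto [-180, 180)."""
    return (np.asarray(x) + 180.0) % 360.0 - 180.0
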