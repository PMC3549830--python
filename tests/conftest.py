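import numpy as np
import pytest

from solvmsm import Configuration, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_configuration(rng, m=4, n=12, frame_index=0, spread=5.0):
    return Configuration(
        solute_coords=rng.uniform(-spread, spread, size=(m, 3)),
        solvent_coords=rng.uniform(-spread, spread, size=(n, 3)),
        frame_index=frame_index,
    )


@pytest.fixture
def random_trajectory(rng):
    frames = [random_configuration(rng, m=3, n=8, frame_index=i) for i in range(6)]
    return Trajectory(frames=frames, lag_time=2.0, trajectory_id="rand")
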