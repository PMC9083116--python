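import numpy as np
import pytest

from unfoldkit import (
    SyntheticConfig,
    Trajectory,
    make_templates,
    make_toy_protein,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def toy():
    return make_toy_protein(30)


@pytest.fixture(scope="session")
def templates(toy):
    return make_templates(toy)


@pytest.fixture(scope="session")
def native_traj(toy, templates):
    """Pure-native trajectory with default jitter, 500 frames."""
    config = SyntheticConfig(
        n_frames=500, occupancies={"native": 1.0}, seed=11
    )
    traj, states = simulate_trajectory(config, toy=toy, templates=templates)
    return traj


@pytest.fixture(scope="session")
def two_state_traj(toy, templates):
    """Native/unfolded mixture 0.7/0.3, 2000 frames."""
    config = SyntheticConfig(
        n_frames=2000,
        occupancies={"native": 0.7, "unfolded": 0.3},
        seed=23,
    )
    return simulate_trajectory(config, toy=toy, templates=templates)


def static_trajectory(model, coords, n_frames=12, temperature=300.0):
    """Frames all identical to the given coordinate set."""
    stack = np.repeat(coords[None], n_frames, axis=0)
    return Trajectory(model, stack, temperature_label=temperature)
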