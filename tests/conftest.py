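import numpy as np
import pytest

from liftsim.body import Anthropometry, build_body
from liftsim.motion import TaskSpec, generate_lift_trajectory


@pytest.fixture(scope="session")
def anthro():
    return Anthropometry(stature=1.76, body_mass=70.4)


@pytest.fixture(scope="session")
def model(anthro):
    return build_body(anthro)


@pytest.fixture(scope="session")
def lift_task():
    return TaskSpec(box_mass=21.0, box_dims=(0.44, 0.26, 0.14),
                    platform_height=1.46,
                    grip_mode="two_lateral_handles", sequence_type="lift")


@pytest.fixture(scope="session")
def short_lift(anthro, lift_task, model):
    """Coarse lift used by the simulation tests (11 frames at 5 Hz)."""
    return generate_lift_trajectory(anthro, lift_task, duration=2.0,
                                    rate=5.0, seed=1, model=model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
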