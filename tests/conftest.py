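import numpy as np
import pytest

from porescan import ScenarioSpec, generate_scaffold, generate_trajectory


@pytest.fixture(scope="session")
def scaffold():
    """Reference pore scaffold (topology, coordinates)."""
    return generate_scaffold()


@pytest.fixture(scope="session")
def lesion_scaffold():
    return generate_scaffold(lesion=True)


@pytest.fixture(scope="session")
def hop_traj():
    """Noiseless backbone-translocation replica (planted 7.0 Å hop)."""
    return generate_trajectory(
        ScenarioSpec(kind="backbone_translocation", noise_sigma=0.0, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31)))).as_matrix()
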