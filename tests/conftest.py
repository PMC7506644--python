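import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import geomexpr as gx

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def template():
    return gx.neutral_template()


@pytest.fixture(scope="session")
def small_faces():
    """Small synthetic dataset: 12 faces per expression, fixed seed."""
    return gx.generate_dataset(gx.SyntheticConfig(n_per_class=12, rng_seed=3))


@pytest.fixture(scope="session")
def small_matrix(small_faces):
    return gx.extract_matrix(small_faces)


def random_rotation(rng):
    """Uniform random 3D rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
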