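import numpy as np
import pytest
import trimesh
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cochleafit import phantom


@pytest.fixture(scope="session")
def default_specimen():
    return phantom.generate_specimen()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-specimen cohort used by several shape-model tests."""
    return phantom.sample_cohort(6, seed=11, mixed_sides=False)


@pytest.fixture(scope="session")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=4, radius=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
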