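import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roicurate as rc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_simspec():
    """Small, fast simulation geometry for unit tests."""
    return rc.SimSpec(
        n_rois=60,
        fov=rc.FOVGeometry(32, 32, 120, 5.0),
        footprint_radius=3.0,
        seed=7,
    )


@pytest.fixture
def small_collection(small_simspec):
    collection, _ = rc.make_simulated_ground_truth(small_simspec)
    return collection


@pytest.fixture
def small_preprocess():
    return rc.PreprocessSpec(crop_size=20, trace_len=100)


@pytest.fixture
def small_dataset(small_collection, small_preprocess):
    return rc.assemble_dataset(small_collection, small_preprocess, seed=3)
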