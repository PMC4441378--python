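import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nicheevo as ne

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# 50x50 cells at 0.25 degrees over the western Mediterranean
EXTENT = (-5.0, 7.5, 33.0, 45.5)
RESOLUTION = 0.25


@pytest.fixture(scope="session")
def stacks():
    return ne.generate_monthly_stacks(extent=EXTENT, resolution=RESOLUTION, seed=2)


@pytest.fixture(scope="session")
def predictors(stacks):
    return ne.build_predictor_set(stacks)


@pytest.fixture(scope="session")
def reference_tree():
    return ne.build_reference_tree()


@pytest.fixture(scope="session")
def pooled_scores():
    """Two well-separated Gaussian clouds in a 2-D score space plus a broad
    background covering both, for direct overlap-machinery tests."""
    rng = np.random.default_rng(42)
    occ1 = rng.normal([-2.0, 0.0], 0.5, size=(60, 2))
    occ2 = rng.normal([2.0, 0.0], 0.5, size=(60, 2))
    background = rng.uniform([-4.0, -3.0], [4.0, 3.0], size=(1500, 2))
    return occ1, occ2, background
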