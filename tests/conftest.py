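import numpy as np
import pytest

from gliotrack import SyntheticCohortSpec, make_ellipsoid_mask, simulate_cohort


@pytest.fixture(scope="session")
def sphere_mask():
    """Digitized solid sphere, radius 10 mm, 1 mm isotropic spacing."""
    return make_ellipsoid_mask((10.0, 10.0, 10.0), (1.0, 1.0, 1.0), frame_id="sphere-r10")


@pytest.fixture(scope="session")
def default_cohort():
    """Small synthetic cohort at study noise levels, fixed seed."""
    spec = SyntheticCohortSpec(n_progression=12, n_stable=10, n_control=4, seed=11)
    volumes, labels, truth = simulate_cohort(spec)
    return spec, volumes, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
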