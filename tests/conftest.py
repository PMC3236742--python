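import numpy as np
import pytest

from neuropcr import CohortSpec, simulate_contrast_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A compact strong-signal cohort spec reused across test modules."""
    return CohortSpec(grid_dims=(10, 10, 6), cluster_voxels=30, seed=7)


@pytest.fixture(scope="session")
def cohort(small_spec):
    """(records, truth, contrast_sets) for the small strong-signal cohort."""
    return simulate_contrast_cohort(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
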