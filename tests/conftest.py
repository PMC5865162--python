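import numpy as np
import pytest

from radsubtypes.features import extract_feature_table
from radsubtypes.synthetic import (
    CohortSpec, default_archetypes, generate_cohort, make_atlas,
)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects=12, random_seed=0)


@pytest.fixture(scope="session")
def atlas(small_spec):
    return make_atlas(small_spec.volume_shape)


@pytest.fixture(scope="session")
def small_cohort(small_spec, archetypes):
    studies, clinical = generate_cohort(small_spec, archetypes)
    return studies, clinical


@pytest.fixture(scope="session")
def small_table(small_cohort, atlas):
    studies, _ = small_cohort
    return extract_feature_table(studies, atlas)


@pytest.fixture(scope="session")
def blobs():
    """Three well-separated Gaussian blobs (planted partition)."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([rng.normal(c, 0.4, size=(30, 2)) for c in centers])
    truth = np.repeat([0, 1, 2], 30)
    return X, truth


@pytest.fixture(scope="session")
def highdim_blobs():
    """Three planted clusters in 10 dimensions (disjoint 3-feature shifts),
    emulating the geometry of a multi-feature radiomic table."""
    rng = np.random.default_rng(0)
    centers = np.zeros((3, 10))
    for i in range(3):
        centers[i, i * 3:(i + 1) * 3] = 3.0
    X = np.vstack([rng.normal(c, 1.0, size=(30, 10)) for c in centers])
    truth = np.repeat([0, 1, 2], 30)
    return X, truth
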