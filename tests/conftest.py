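import numpy as np
import pytest

from pairseg import (
    GridSpec,
    ProbabilisticMaps,
    UncertaintyProfile,
    sample_probmaps,
    schedule_pairs,
    simulate_responses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid6():
    return GridSpec(6)


@pytest.fixture
def random_maps(rng):
    """Random valid K=3 maps on a 6x6 grid."""
    values = rng.dirichlet(np.ones(3), size=36).reshape(6, 6, 3)
    return ProbabilisticMaps.from_values(values)


@pytest.fixture
def moderate_truth():
    """Moderate-uncertainty K=3 ground truth on a 10x10 grid."""
    return sample_probmaps(
        GridSpec(10), 3, UncertaintyProfile(level=0.5, spatial_scale=1.5), seed=1
    )


@pytest.fixture
def small_dataset(grid6):
    truth = sample_probmaps(grid6, 3, UncertaintyProfile(level=0.4), seed=3)
    pairset = schedule_pairs(grid6, 3, seed=4)
    return truth, simulate_responses(truth, pairset, n_blocks=10, seed=5)
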