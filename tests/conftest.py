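import numpy as np
import pytest

from assoa import PlantedSpec, SearchSpace, generate_planted, generate_separable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return SearchSpace.box(2, 0.0, 1.0)


@pytest.fixture
def box10():
    return SearchSpace.box(10, -5.0, 5.0)


@pytest.fixture(scope="session")
def planted_small():
    """120 samples, 6 features (2 informative + 4 noise), 2 classes."""
    return generate_planted(
        PlantedSpec(n_samples=120, n_features=6, k_informative=2, delta=3.0, seed=100)
    )


@pytest.fixture(scope="session")
def separable_data():
    return generate_separable(200, 10, margin=1.0, seed=200)
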