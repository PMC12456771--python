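import numpy as np
import pytest

from skelphen import SyntheticPlantSpec, generate_plant


@pytest.fixture(scope="session")
def default_plant():
    """One default synthetic seedling with ground truth (seed fixed)."""
    spec = SyntheticPlantSpec(seed=42)
    cloud, truth = generate_plant(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def light_plant():
    """A lower-density plant for fast end-to-end tests."""
    spec = SyntheticPlantSpec(seed=5, points_per_m2=8e5, n_leaves=6)
    cloud, truth = generate_plant(spec)
    return spec, cloud, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
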