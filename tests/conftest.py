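import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strokedti.atlas import LabelVolume, load_ontology
from strokedti.synthetic import make_atlas

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture(scope="session")
def atlas48():
    """Default synthetic atlas (ontology, labels) shared across tests."""
    return make_atlas()


@pytest.fixture()
def random_labels(ontology):
    """Factory for random small label volumes over the real region ids."""

    def make(seed: int, shape=(16, 16, 16), midline=8):
        rng = np.random.default_rng(seed)
        ids = [0] + [r.region_id for r in ontology]
        grid = rng.choice(ids, size=shape).astype(np.int32)
        return LabelVolume(grid=grid, voxel_size_mm=(0.2, 0.2, 0.2),
                           midline_index=midline)

    return make
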