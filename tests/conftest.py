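import numpy as np
import pytest

from nucoloc import SimulationConfig, generate_field


@pytest.fixture(scope="session")
def small_config():
    """Compact field used by most tests: 6 nuclei on a 256x256 field."""
    return SimulationConfig(
        field_shape=(256, 256), n_nuclei=6, nucleus_axes_range=(12.0, 18.0), seed=11
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return generate_field(small_config)


@pytest.fixture(scope="session")
def noise_free_field():
    cfg = SimulationConfig(
        field_shape=(256, 256),
        n_nuclei=6,
        nucleus_axes_range=(12.0, 18.0),
        noise_sigma=0.0,
        seed=21,
    )
    return generate_field(cfg)


def collect_cells(configs, score=None):
    """Generate fields and yield (field, truth) pairs for each config."""
    for cfg in configs:
        yield generate_field(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
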