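import numpy as np
import pytest
from hypothesis import settings

from dsgc_occlusion import ExperimentConfig, GeometryConfig, build_mosaic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_mosaic():
    """Full-size mosaic (1000 cells per subtype) shared across read-only tests."""
    return build_mosaic(GeometryConfig(), seed=1234)


@pytest.fixture()
def small_config():
    """Reduced-size configuration for pipeline smoke tests."""
    cfg = ExperimentConfig(seed=99, n_blocks=2, n_reps=2)
    cfg.geometry.n_cells = 150
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
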