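import numpy as np
import pytest

from silentwm.config import ModelConfig, PopulationConfig
from silentwm.visual_basis import make_basis
from silentwm.wm_model import WMModel


def small_config() -> ModelConfig:
    """A scaled-down model for structural tests (fast to build)."""
    cfg = ModelConfig()
    cfg.n_gabors = 200
    cfg.sensory = PopulationConfig(200, 24, 0.01, 0.1)
    cfg.memory = PopulationConfig(300, 24, 0.01, 0.1)
    cfg.comparison = PopulationConfig(200, 4, 0.01, 1.0)
    cfg.decision = PopulationConfig(100, 1, -1.0, 1.0)
    cfg.basis_step_deg = 2.0
    return cfg.validate()


@pytest.fixture(scope="session")
def basis_small():
    """A 200-filter visual basis, shared across visual-code tests."""
    return make_basis(n_gabors=200, rng=11, step_deg=2.0)


@pytest.fixture(scope="session")
def model_full():
    """The full two-module model at published sizes (built once)."""
    return WMModel(ModelConfig(), seed=42)


@pytest.fixture(scope="session")
def model_small():
    return WMModel(small_config(), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
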