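import numpy as np
import pytest

from craniomark.config import PipelineConfig
from craniomark.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    return PipelineConfig.desk_scale()


@pytest.fixture(scope="session")
def desk_cohort():
    """Twelve desk-scale phantom cases shared across tests."""
    spec = PhantomSpec.desk_scale(seed=42, n_cases=12)
    volumes, tables = generate_cohort(spec)
    return spec, volumes, tables


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
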