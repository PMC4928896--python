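import numpy as np
import pytest

from myxospread import ModelParameters


@pytest.fixture(scope="session")
def soft_agar() -> ModelParameters:
    """Soft-agar parameter set (rates converted from per-hour captions)."""
    return ModelParameters.with_hour_rates(gmax=0.173, alpha=19.0, beta=16.0)


@pytest.fixture(scope="session")
def soft_agar_dn0(soft_agar) -> ModelParameters:
    """Same set with non-diffusing nutrients (phase-space reduction regime)."""
    return soft_agar.evolve(DN=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
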