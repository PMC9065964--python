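import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import woo

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig3_dmn():
    """The worked dichotomous Markov noise environment."""
    return woo.DMNParams(E_low=0.0, E_high=1.0, k_low=0.1, k_high=0.2,
                         dt=0.01, n_steps=200_000)


@pytest.fixture(scope="session")
def fig3_organism():
    """Linear tolerance growth from T0 = 1/6 at rate 0.1 (gap 5/6)."""
    return woo.ToleranceModel(T0=1.0 / 6.0, lam=0.1, growth_type="linear")


@pytest.fixture(scope="session")
def long_dmn_trajectory(fig3_dmn):
    """One long seeded DMN realization shared across statistical tests."""
    params = woo.DMNParams(**{**fig3_dmn.__dict__, "n_steps": 2_000_000})
    return woo.generate_dmn(params, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
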