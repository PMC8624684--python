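import numpy as np
import pytest
from hypothesis import settings

from mscog.simulate import OUTCOMES, SimulationConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One modest cohort under default study conditions."""
    return generate_cohort(SimulationConfig(n_subjects=80, seed=42))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic trajectories lying exactly on the population spline."""
    cfg = SimulationConfig(
        n_subjects=30,
        seed=7,
        residual_sd=0.0,
        random_intercept_sd=0.0,
        random_slope_sd=0.0,
        covariate_effects={},
        period_slopes={o: (0.08, -0.03, -0.03) for o in OUTCOMES},
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
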