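import numpy as np
import pytest

from kfrs import SimulationConfig, fit_fine_gray, simulate_cohort


@pytest.fixture(scope="session")
def female_cohort():
    """Moderate synthetic female cohort under default study conditions."""
    return simulate_cohort(SimulationConfig(n=20000, sex="female", seed=7))


@pytest.fixture(scope="session")
def female_fit(female_cohort):
    fit = fit_fine_gray(female_cohort)
    assert fit.converged
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
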