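import numpy as np
import pytest

from irtscore import (
    EmConfig,
    SimulationConfig,
    load_reference_grm,
    load_reference_nrm,
    normal_grid,
    simulate_grm_cohort,
    simulate_nrm_cohort,
)


@pytest.fixture(scope="session")
def grid():
    """Coarse-but-adequate quadrature used throughout the suite."""
    return normal_grid(31, 5.0)


@pytest.fixture(scope="session")
def fine_grid():
    return normal_grid(201, 6.0)


@pytest.fixture(scope="session")
def em_config():
    return EmConfig(tol_loglik=1e-6, max_iter=400)


@pytest.fixture(scope="session")
def reference_grm():
    return load_reference_grm("pooled")


@pytest.fixture(scope="session")
def reference_grm_dif():
    return load_reference_grm("dif")


@pytest.fixture(scope="session")
def reference_nrm():
    return load_reference_nrm("pooled")


@pytest.fixture(scope="session")
def reference_nrm_dif():
    return load_reference_nrm("dif")


@pytest.fixture(scope="session")
def grm_cohort_small():
    """A 400-respondent cohort from the reference GRM values."""
    return simulate_grm_cohort(SimulationConfig(n=400, seed=11))


@pytest.fixture(scope="session")
def grm_cohort_large():
    """A 2,000-respondent cohort from the reference GRM values."""
    return simulate_grm_cohort(SimulationConfig(n=2000, seed=42))


@pytest.fixture(scope="session")
def nrm_cohort():
    return simulate_nrm_cohort(SimulationConfig(n=1200, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
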