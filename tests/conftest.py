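import pytest

from slideproteo.io import packaged_signatures
from slideproteo.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sigs():
    return packaged_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for structural and IO tests."""
    cfg = SimConfig(n_samples=16, n_proteins=400, detection_capacity=300.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort68():
    """Default-scale cohort (68 samples, 9000 proteins)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort200():
    """Large cohort for the suppression-phenomenology properties."""
    return simulate_cohort(SimConfig(n_samples=200, seed=5))
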