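import numpy as np
import pytest
from hypothesis import settings

from poolancestry.intensity import estimate_pool_afs
from poolancestry.simulate import SimConfig, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_study():
    """Clean two-pool study, small enough for fast unit tests."""
    return simulate_study(SimConfig(n_snps=800, n_individuals=200, seed=101))


@pytest.fixture(scope="session")
def small_pool_af(small_study):
    return estimate_pool_afs(small_study.geometry, small_study.replicate_points)


@pytest.fixture(scope="session")
def corrupt_study():
    """Four-pool study with 5% corrupted SNPs, for QC tests."""
    return simulate_study(
        SimConfig(n_snps=4000, n_individuals=250, n_pools=4, corrupt_fraction=0.05, seed=11)
    )
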