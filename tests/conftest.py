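import numpy as np
import pytest

from netlag.cohort import CohortConfig, simulate_cohort
from netlag.core import VoxelGrid


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid.isotropic((12, 14, 12), 3.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but complete three-group cohort shared across tests."""
    cfg = CohortConfig(
        group_sizes={"HC": 6, "HET": 4, "HOM": 4},
        grid_dims=(12, 14, 12),
        T=96,
        blob_sigma_mm=3.5,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
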