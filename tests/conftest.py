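import numpy as np
import pytest

from gesse.echo_model import EchoTrainSpec, TissueParams
from gesse.phantom import TractSpec, default_tracts, generate_voxel_table

TABLE1_FIT3 = (22.08, -6.06, 3.49, 0.0)
TABLE1_FIT1_INTERCEPT = 21.26
TABLE1_FIT1_SLOPE = 5.34


@pytest.fixture(scope="session")
def spec() -> EchoTrainSpec:
    return EchoTrainSpec.default()


@pytest.fixture
def tissue() -> TissueParams:
    return TissueParams(M0=1000.0, R2=25.0, R2prime=5.0)


@pytest.fixture(scope="session")
def small_tracts() -> list[TractSpec]:
    """Four-tract population for fast regression tests."""
    return [
        TractSpec(0, "a", 3.0, (0.0, 0.0, 1.0), 4.0, n_voxels=500),
        TractSpec(1, "b", 4.0, (1.0, 0.0, 0.0), 4.0, n_voxels=500),
        TractSpec(2, "c", 5.0, (1.0, 0.0, 1.0), 4.0, n_voxels=500),
        TractSpec(3, "d", 6.0, (0.0, 1.0, 1.0), 4.0, n_voxels=500),
    ]


@pytest.fixture(scope="session")
def noiseless_table(small_tracts):
    return generate_voxel_table(TABLE1_FIT3, small_tracts, sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def default_table():
    """The full 20-tract, 2500-voxel-per-tract table with rate noise."""
    return generate_voxel_table(TABLE1_FIT3, default_tracts(), sigma=1.5, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
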