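import numpy as np
import pytest

from radaug.types import PhantomConfig
from radaug.phantom import generate_cohort, render_case


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A fast 16-voxel-cubed phantom configuration used across tests."""
    return PhantomConfig(
        n_majority=4,
        n_minority=2,
        volume_shape=(16, 16, 16),
        tumor_radius_range_mm=(3.0, 4.5),
        master_seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def case32():
    """One 32-voxel-cubed case for full-schema and augmentation tests."""
    cfg = PhantomConfig(n_majority=2, n_minority=2, master_seed=7)
    return render_case(0, np.random.SeedSequence(123), cfg, case_id="case32")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
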