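import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from batscan.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 6-patient phantom cohort shared across tests."""
    return generate_cohort(PhantomSpec(n_patients=6, rng_seed=3))


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_levels(rng, shape, ng, p_background=0.2):
    """A random discretized ROI lattice: levels 1..ng, 0 = outside."""
    levels = rng.integers(1, ng + 1, size=shape)
    levels[rng.random(shape) < p_background] = 0
    if not (levels > 0).any():
        levels.flat[0] = 1
    return levels.astype(np.int32)
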