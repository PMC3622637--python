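import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import permalign as pa

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

TOY_M = 15


@pytest.fixture(scope="session")
def toy_genome():
    """The toy scale: a 20 000-base random reference, 15-mers."""
    return pa.generate_genome(20_000, seed=20230)


@pytest.fixture(scope="session")
def toy_library(toy_genome):
    return pa.build_library(toy_genome, TOY_M)


@pytest.fixture(scope="session")
def toy_indexes(toy_library):
    return pa.build_indexes(toy_library, 8, seed=11)


@pytest.fixture(scope="session")
def small_library():
    """A 500-base genome small enough for brute-force oracles."""
    return pa.build_library(pa.generate_genome(500, seed=7), 12)


@pytest.fixture(scope="session")
def small_index(small_library):
    return pa.build_index(small_library, pa.random_permutation(12, seed=3))


def explicit_sorted_keys(index):
    """Independent view of an index: the permuted M-mers as explicit strings,
    in sorted-array order (used by scan oracles)."""
    return [index.key(int(p)) for p in index.order]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
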