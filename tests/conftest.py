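import numpy as np
import pytest

import cryotrace as ct


@pytest.fixture(scope="session")
def small_protein():
    """A 40-residue helix/loop/strand protein used across modules."""
    return ct.generate_synthetic_protein(
        [("helix", 15), ("loop", 5), ("sheet", 10), ("loop", 10)], seed=42)


@pytest.fixture(scope="session")
def small_map(small_protein):
    return ct.simulate_density(small_protein, resolution=3.0)


@pytest.fixture(scope="session")
def small_oracle(small_protein, small_map):
    return ct.oracle_confidence(small_protein, small_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
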