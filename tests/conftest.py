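import numpy as np
import pytest

from condcoloc import SimScenario, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20180524)


@pytest.fixture
def small_geno():
    """200 samples x 40 variants in 4 LD blocks; deterministic."""
    scenario = SimScenario(seed=11, n_samples=200, n_variants=40, block_size=10)
    return simulate_genotypes(scenario)
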