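import numpy as np
import pytest

from commdesign.glv import GLVParameters, SpeciesRegistry
from commdesign.synthetic import SyntheticConfig, generate_ground_truth, make_registry


@pytest.fixture(scope="session")
def registry5() -> SpeciesRegistry:
    return make_registry(5, 1)


@pytest.fixture(scope="session")
def registry8() -> SpeciesRegistry:
    return make_registry(8, 2)


@pytest.fixture(scope="session")
def truth8():
    """Ground-truth parameter set for the standard 8-species / 2-producer pool."""
    cfg = SyntheticConfig(
        n_species=8, n_bp=2, production_sparsity=4, contamination_rate=0.0, seed=7
    )
    return generate_ground_truth(cfg)


def random_glv(n: int, seed: int, scale: float = 0.4) -> GLVParameters:
    """A random, bounded gLV parameter set for property tests."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.1, 0.7, n)
    a = rng.uniform(-scale, scale / 4, (n, n))
    np.fill_diagonal(a, -rng.uniform(0.3, 1.5, n))
    return GLVParameters(r, a)
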