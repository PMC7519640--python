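import numpy as np
import pytest

import serrscell as sc
from serrscell.config import RunConfig, PoolsConfig
from serrscell.pipeline import build_reference_pools
from serrscell.scoring import ReferenceLibrary
from serrscell.synthetic import NoiseModel


@pytest.fixture(scope="session")
def library() -> ReferenceLibrary:
    """Default three-reporter reference library on the default grid."""
    return ReferenceLibrary(spectra=sc.default_reference_library())


@pytest.fixture(scope="session")
def default_pools(library):
    """Moderate-size gated reference pools under default noise (seeded)."""
    cfg = RunConfig(pools=PoolsConfig(n_lncap=150, n_u251=150, n_pbmc=1500))
    rng = np.random.default_rng(12345)
    pools, areas = build_reference_pools(cfg, library, NoiseModel(), rng)
    return pools, areas


@pytest.fixture(scope="session")
def default_forest(default_pools):
    """Forest trained on the default pools (200 trees, fixed seed)."""
    pools, _ = default_pools
    return sc.train_forest(pools.all_rows(), sc.ForestConfig(n_trees=200, seed=7))
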