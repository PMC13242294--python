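import numpy as np
import pytest

from stclust.core_io import RunConfig
from stclust.domain_clustering import run_variant
from stclust.synthetic import SimConfig, simulate_tissue


@pytest.fixture(scope="session")
def sim_default():
    """30x30 hex lattice, 4 laminar domains, strong marker effect."""
    return simulate_tissue(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_null():
    """Same lattice with zero marker effect (no spatial signal)."""
    return simulate_tissue(SimConfig(marker_log2_fc=0.0, seed=0))


@pytest.fixture(scope="session")
def sim_small():
    """Smaller, faster simulation for pipeline-level tests."""
    return simulate_tissue(
        SimConfig(n_rows=15, n_cols=15, n_domains=3, n_genes=120, n_markers_per_domain=15, seed=1)
    )


@pytest.fixture(scope="session")
def act_strong(sim_default):
    config = RunConfig(variant="ACT", n_clusters=4, seed=0)
    return run_variant(sim_default, config)


@pytest.fixture(scope="session")
def act_null(sim_null):
    config = RunConfig(variant="ACT", n_clusters=4, seed=0)
    return run_variant(sim_null, config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
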