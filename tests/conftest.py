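import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dsbstrand.simulate import (
    DSBParams,
    GeneParams,
    SimulationConfig,
    simulate_all,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle (seed 1): 200 genes, 40 DSBs, full tracks."""
    cfg = SimulationConfig(seed=1)
    genes, sites, bundle = simulate_all(cfg)
    return cfg, genes, sites, bundle


@pytest.fixture(scope="session")
def tiny_noiseless_bundle():
    """Five expressed genes, one promoter TC-DSB, no noise, no background:
    the analytic construction for exact strand-geometry checks."""
    cfg = SimulationConfig(seed=2)
    cfg.noise.enabled = False
    cfg.qdrip.background = 0.0
    cfg.genes = GeneParams(n_genes=5, fraction_silent=0.0)
    cfg.dsbs = DSBParams(contexts={"promoter": 1})
    genes, sites, bundle = simulate_all(cfg)
    return cfg, genes, sites, bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
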