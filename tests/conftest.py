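import numpy as np
import pandas as pd
import pytest

from holoseq.simulate import SimulationConfig, default_design, gen_counts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_host=200, n_symbiont=200, n_genes=400,
                            n_deg_site=30, n_deg_clade=30,
                            module_spec=((60, 0.8),), n_snps=300)


@pytest.fixture(scope="session")
def counts_fixture():
    """Counts/FPKM with planted site and clade DEGs and one module."""
    cfg = SimulationConfig(seed=21, n_genes=600, n_deg_site=40, n_deg_clade=40,
                           module_spec=((80, 0.8),))
    design = default_design(cfg)
    counts, fpkm, truth = gen_counts(cfg, design)
    return cfg, design, counts, fpkm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
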