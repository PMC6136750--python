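import numpy as np
import pytest

import bayesvar as bv


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """3-gene panel (one sparse gene) with evidence and ground truth."""
    cfg = bv.SimulationConfig(
        n_genes=3,
        gene_sizes=[25, 20, 12],
        missing_rate=0.05,
        evidence_rate=0.8,
        evidence_consistency=0.97,
        seed=5,
    )
    panel, truth = bv.simulate_panel(cfg)
    evidence = bv.simulate_evidence(panel, cfg)
    return panel, evidence, truth, cfg


@pytest.fixture(scope="session")
def normalized_panel(small_sim):
    panel, evidence, truth, _ = small_sim
    norm, cols = bv.normalize_panel(panel, k=5)
    return norm, cols, evidence, truth


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down MCMC/selection settings to keep tests quick."""
    return bv.RunConfig(
        seed=11, burn_in=150, n_samples=300, penalties=(2, 4, 6, 8), cv_folds=3
    )
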