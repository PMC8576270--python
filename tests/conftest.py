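import numpy as np
import pytest

from inflammeth.simdata import SimConfig, simulate_all


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Small, fast cohort: one 120-kb chromosome, 12 genes, 5 DMRs/context."""
    return SimConfig(
        n_chroms=1,
        chrom_length=120_000,
        n_genes=12,
        n_planted_dmrs=5,
        n_mice=3,
        n_germline_variants=60,
        n_somatic_variants=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    return simulate_all(tiny_cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default scenario: 20 planted DMRs per context, delta 0.4 on a
    CG baseline of 0.2, coverage 30."""
    return simulate_all(SimConfig(seed=101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
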