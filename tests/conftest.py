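import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from haplodiff.simulate import SimConfig, simulate_diploid, simulate_expression


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact diploid world: 200 kb, 30 background genes + 4 family copies."""
    return SimConfig(
        genome_length=200_000,
        n_contigs=2,
        n_genes=30,
        snp_rate=1e-3,
        indel_rate=2e-4,
        sv_rate=2e-5,
        n_hap_specific_genes=3,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    return simulate_diploid(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_world):
    _, _, truth = small_world
    return simulate_expression(small_cfg, truth)
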