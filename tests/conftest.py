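from __future__ import annotations

import numpy as np
import pytest

from ervamp.insilico_pcr import PcrScanParams, PrimerPair
from ervamp.simulate import SimConfig, build_genome, simulate_reads


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A scaled-down cohort: 8 loci, 3 chromosomes, 4 vs 4 samples,
    one planted 4-fold up and one 2-fold down effect."""
    return SimConfig(seed=11, n_loci=8, consensus_len=300, n_chroms=3,
                     reads_per_sample=600, group_sizes=(4, 4),
                     planted_effects=((4, 4.0), (6, 0.5)))


@pytest.fixture(scope="session")
def small_scan_params() -> PcrScanParams:
    # product window sized to the 300 bp consensus of the small cohort
    return PcrScanParams(min_amplicon_len=100, max_amplicon_len=700)


@pytest.fixture(scope="session")
def small_genome(small_sim_config):
    genome, truth = build_genome(small_sim_config)
    return genome, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim_config, small_genome):
    genome, truth = small_genome
    reads_by_sample, truth = simulate_reads(genome, truth, small_sim_config)
    return genome, truth, reads_by_sample


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
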