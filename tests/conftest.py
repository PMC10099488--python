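import numpy as np
import pytest

from lakerad.synthetic_data import (
    DemographyConfig,
    default_barcodes,
    generate_ddrad_reads,
    simulate_metapopulation,
)


@pytest.fixture(scope="session")
def small_sample():
    """A small 1-sea + 2-lake metapopulation with planted problem loci."""
    cfg = DemographyConfig(
        n_lakes=2,
        n_sea=1,
        n_loci=60,
        seed=5,
        mutation_rate=1e-7,
        connection_scaling={"lake1": 0.1, "lake2": 0.8},
        n_contaminant=4,
        n_repeat=2,
    )
    return simulate_metapopulation(cfg, {"sea1": 5, "lake1": 5, "lake2": 5})


@pytest.fixture(scope="session")
def small_reads(small_sample):
    barcodes = default_barcodes(small_sample.individuals)
    reads, depth = generate_ddrad_reads(
        small_sample, barcodes, depth_mean=10, error_rate=0.005, seed=9
    )
    return reads, depth, barcodes


@pytest.fixture(scope="session")
def clean_reads(small_sample):
    """Error-free reads at fixed generous depth from the same sample."""
    barcodes = default_barcodes(small_sample.individuals)
    reads, depth = generate_ddrad_reads(
        small_sample,
        barcodes,
        depth_mean=12,
        error_rate=0.0,
        seed=11,
        dispersion=1e6,  # effectively fixed depth
    )
    return reads, depth, barcodes


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
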