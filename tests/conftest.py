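import numpy as np
import pytest

from chalkmap import synthetic_data as sd


@pytest.fixture(scope="session")
def two_chrom_config() -> sd.SimConfig:
    return sd.SimConfig(
        n_lines=192,
        chromosomes=[sd.ChromosomeSpec("Chr01", 43_270_000, 116.1),
                     sd.ChromosomeSpec("Chr02", 35_940_000, 110.8)],
        seed=42,
    )


@pytest.fixture(scope="session")
def two_chrom_genomes(two_chrom_config):
    return sd.simulate_ril_genomes(two_chrom_config)


@pytest.fixture(scope="session")
def two_chrom_observations(two_chrom_config, two_chrom_genomes):
    return sd.simulate_gbs_observations(two_chrom_genomes, two_chrom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
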