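import numpy as np
import pytest

from psychromark import markers, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale configuration used by most unit tests."""
    return simulate.SimConfig(
        seed=11,
        n_genomes_per_group=(8, 4, 6),
        n_families_core=30,
        n_families_group_specific=10,
        n_families_accessory=15,
        n_metagenomes=12,
        enriched_sample_count=2,
    )


@pytest.fixture(scope="session")
def small_collection(small_cfg):
    return simulate.simulate_genome_collection(small_cfg)


@pytest.fixture(scope="session")
def small_markers(small_collection):
    _, matrix, _, truth = small_collection
    return markers.group_specific_genes(matrix, truth.genome_groups)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
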