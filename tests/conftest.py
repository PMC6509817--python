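import pytest

from mutscreen import Pedigree, SimConfig, simulate_genome, simulate_pedigree_variants


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Genome, gene models, per-strain variants and ledger of one small
    synthetic lineage, shared across tests (nothing mutates it)."""
    genome, models = simulate_genome(small_config)
    strains, ledger = simulate_pedigree_variants(small_config, genome, models)
    return genome, models, strains, ledger


@pytest.fixture(scope="session")
def pedigree():
    return Pedigree("SS-II", ("NG14", "RUT-C30"))
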