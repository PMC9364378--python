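import pytest

from corephylo.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A small two-group clade whose divergences straddle the 97% species
    threshold (within-species ~99.5%, between-species ~94.5%)."""
    return SimConfig(
        n_groups=2,
        species_per_group=3,
        genomes_per_species=2,
        core_panel_size=60,
        accessory_pool_size=150,
        mean_gene_length_codons=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No annotation noise, no splits, no rearrangements, no drafts: gene
    content and architecture equal the truth tables exactly."""
    return SimConfig(
        n_groups=2,
        species_per_group=2,
        genomes_per_species=2,
        core_panel_size=40,
        accessory_pool_size=80,
        mean_gene_length_codons=100,
        rearrangement_rate=0.0,
        draft_fraction=0.0,
        gene_split_probability=0.0,
        noise_annotation_rates={},
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)
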