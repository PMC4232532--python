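import pytest

from divergekit.simulate import (SimulationConfig, plant_variants,
                                 simulate_allele_counts, simulate_genome)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def genome_models(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def planted(genome_models, default_config):
    genome, models = genome_models
    return plant_variants(genome, models, default_config)


@pytest.fixture(scope="session")
def allele_counts(genome_models, planted, default_config):
    _, models = genome_models
    out = {}
    for genotype, (truth, mutated) in planted.items():
        out[genotype] = simulate_allele_counts(mutated, models, truth,
                                               default_config, genotype)
    return out


@pytest.fixture(scope="session")
def small_genome():
    """A compact two-chromosome system for fast per-test simulation."""
    cfg = SimulationConfig(seed=3, n_chromosomes=2, n_genes=12,
                           chrom_length=60_000)
    genome, models = simulate_genome(cfg)
    return cfg, genome, models
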