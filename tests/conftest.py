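import pytest

from cinslnet import SimulationConfig, simulate_gene_universe


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale study: 200 genes, 3 planted hubs, 2 complexes."""
    return SimulationConfig(
        n_genes=200, cin_fraction=0.2, n_hubs=3, hub_cin_degree=10,
        background_edge_prob=0.05, n_complexes=2, complex_size=3,
        n_null_pairs=5, seed=11,
    )


@pytest.fixture
def noiseless_config(small_config) -> SimulationConfig:
    """Same study with every noise source switched off."""
    import dataclasses
    return dataclasses.replace(
        small_config, score_noise_sd=0.0, colony_noise_cv=0.0,
        proliferation_noise_cv=0.0)


@pytest.fixture
def small_universe(small_config):
    return simulate_gene_universe(small_config)
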