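import pytest

from bsaed.synthetic_data import SimConfig, simulate_phenotypes, simulate_pools


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A quick-to-simulate config with a planted locus and some triallelic sites."""
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        n_snps_per_chrom=1500,
        causal_chrom=1,
        causal_center_bp=5_000_000,
        causal_halfwidth_bp=600_000,
        mean_depth=30,
        triallelic_fraction=0.01,
        n_animals=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    sites, truth = simulate_pools(small_config)
    return sites, truth


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_sim):
    _, truth = small_sim
    return simulate_phenotypes(small_config, truth)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config, small_sim, small_phenotypes):
    from bsaed.synthetic_data import write_fixture_bundle

    sites, truth = small_sim
    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(
        sites, truth, small_phenotypes, out, seed=small_config.seed
    )
    return out, manifest
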