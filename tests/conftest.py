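import pytest

from snpfunnel.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic benchmark (shared across tests; read-only)."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture()
def tiny_config():
    """A fast, small simulation for plumbing tests (not for power checks)."""
    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length_bp=3_000_000,
        n_snps_per_chrom=300,
        n_genes=8,
        n_causal_genes_per_trait=3,
        min_causal_gene_spacing_bp=600_000,
        n_tracks_per_category=2,
        n_haplotypes=60,
    )


@pytest.fixture(scope="session")
def e2e_runs():
    """Three full simulate->pipeline->recovery runs on the default study
    conditions (seeds 7, 8, 9); shared by the model-power and end-to-end
    recovery checks."""
    from snpfunnel.pipeline import simulate_and_run

    out = []
    for seed in (7, 8, 9):
        out.append(simulate_and_run(SimulationConfig(seed=seed)))
    return out
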