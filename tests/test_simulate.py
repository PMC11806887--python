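import dataclasses
import json

import numpy as np
import pytest

from snpfunnel._rng import child_rng
from snpfunnel.genes import assign_genes
from snpfunnel.simulate import (
    SimulationConfig,
    generate_feature_tracks,
    generate_gene_models,
    generate_genotype_panel,
    generate_summary_stats,
    make_truth,
    simulate_dataset,
    write_dataset,
)


def _r2(a, b):
    return float(np.corrcoef(a.astype(float), b.astype(float))[0, 1] ** 2)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(n_causal_genes_per_trait=99, n_genes=10)
    with pytest.raises(ValueError):
        SimulationConfig(shared_causal_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(enrichment_odds=0)


def test_shared_count_rounds_half_up():
    assert SimulationConfig(n_causal_genes_per_trait=5, shared_causal_fraction=0.5).n_shared_causal == 3
    assert SimulationConfig(n_causal_genes_per_trait=4, shared_causal_fraction=0.5).n_shared_causal == 2
    assert SimulationConfig(n_causal_genes_per_trait=5, shared_causal_fraction=0.0).n_shared_causal == 0


def test_panel_too_small_for_ld():
    with pytest.raises(ValueError, match="panel too small"):
        generate_genotype_panel(SimulationConfig(n_haplotypes=3))


def test_every_snp_maf_within_range(tiny_config):
    panel = generate_genotype_panel(tiny_config)
    freqs = panel.haplotypes.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    lo, hi = tiny_config.maf_range
    assert (maf >= lo).all() and (maf <= hi).all()


def test_same_seed_gives_bit_identical_panel(tiny_config):
    a = generate_genotype_panel(tiny_config)
    b = generate_genotype_panel(tiny_config)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert a.snp_ids == b.snp_ids and np.array_equal(a.positions, b.positions)


def test_within_block_ld_exceeds_cross_block_ld():
    cfg = SimulationConfig(
        seed=1, n_chromosomes=1, chrom_length_bp=2_000_000, n_snps_per_chrom=200,
        ld_block_len_bp=50_000, n_genes=2, n_causal_genes_per_trait=1,
        min_causal_gene_spacing_bp=500_000, n_haplotypes=100,
    )
    panel = generate_genotype_panel(cfg)
    block = (panel.positions - 1) // cfg.ld_block_len_bp
    within, cross = [], []
    for i in range(panel.n_snps - 1):
        r2 = _r2(panel.haplotypes[:, i], panel.haplotypes[:, i + 1])
        (within if block[i] == block[i + 1] else cross).append(r2)
    rng = np.random.default_rng(1)
    for _ in range(300):
        i, j = rng.integers(0, panel.n_snps, size=2)
        if i != j and block[i] != block[j]:
            cross.append(_r2(panel.haplotypes[:, i], panel.haplotypes[:, j]))
    assert np.mean(within) > np.mean(cross)


def _null_config(seed, n_chrom=2, n_snps=5_000):
    return SimulationConfig(
        seed=seed, n_chromosomes=n_chrom, n_snps_per_chrom=n_snps,
        n_causal_genes_per_trait=0, n_genes=8, n_haplotypes=60,
    )


def test_null_pvalues_uniform_by_ks():
    cfg = _null_config(seed=3, n_snps=5_000)  # 2 chrom x 5,000 = 10,000 SNPs
    ds_panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, ds_panel)
    truth = make_truth(cfg, ds_panel, genes, links)
    table = generate_summary_stats(ds_panel, truth, "trait1", cfg)
    p = np.sort(table.df["pvalue"].to_numpy())
    n = len(p)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d = max(np.abs(ecdf_hi - p).max(), np.abs(p - ecdf_lo).max())
    assert d < 1.628 / np.sqrt(n)  # 1% asymptotic critical value


def test_zero_causal_output_equals_pure_uniform_stream():
    cfg = _null_config(seed=5, n_snps=500)
    panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, panel)
    truth = make_truth(cfg, panel, genes, links)
    table = generate_summary_stats(panel, truth, "trait1", cfg)
    ref = child_rng(cfg.seed, "stats-trait1").random(panel.n_snps)
    ref = np.clip(ref, np.finfo(float).tiny, 1.0)
    got = table.df.set_index("snp_id").loc[panel.snp_ids, "pvalue"].to_numpy()
    assert np.array_equal(got, ref)


def test_unknown_trait_rejected(tiny_config):
    panel = generate_genotype_panel(tiny_config)
    genes, links = generate_gene_models(tiny_config, panel)
    truth = make_truth(tiny_config, panel, genes, links)
    with pytest.raises(ValueError, match="unknown trait"):
        generate_summary_stats(panel, truth, "trait9", tiny_config)


def test_causal_pvalues_concentrate_near_zero():
    cfg = SimulationConfig(
        seed=5, n_chromosomes=2, chrom_length_bp=5_000_000, n_snps_per_chrom=2_500,
        n_genes=12, n_causal_genes_per_trait=4, min_causal_gene_spacing_bp=1_000_000,
        causal_p_beta_params=(0.2, 8.0), n_haplotypes=80,
    )
    panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, panel)
    truth = make_truth(cfg, panel, genes, links)
    table = generate_summary_stats(panel, truth, "trait1", cfg)
    df = table.df.set_index("snp_id")
    causal = df.loc[sorted(truth.causal_snp_ids["trait1"]), "pvalue"]
    null = df.drop(index=truth.causal_snp_ids["trait1"])["pvalue"]
    assert causal.median() < null.median()


def test_enrichment_odds_recovered_within_30_percent():
    cfg = SimulationConfig(
        seed=2, n_chromosomes=2, chrom_length_bp=5_000_000, n_snps_per_chrom=2_500,
        n_genes=12, n_causal_genes_per_trait=6, min_causal_gene_spacing_bp=800_000,
        n_causal_snps_per_gene=8, background_overlap_rate=0.1, enrichment_odds=9.0,
        n_haplotypes=80,
    )
    panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, panel)
    truth = make_truth(cfg, panel, genes, links)
    tracks = generate_feature_tracks(panel, truth, cfg)
    causal = truth.all_causal_snp_ids
    a = b = c = d = 0
    for tr in tracks:
        for sid, chrom, pos in zip(panel.snp_ids, panel.chroms, panel.positions):
            hit = tr.covers(chrom, int(pos) - 1)
            if sid in causal:
                a, b = a + hit, b + (not hit)
            else:
                c, d = c + hit, d + (not hit)
    odds_ratio = (a / b) / (c / d)
    assert 0.7 * 9.0 <= odds_ratio <= 1.3 * 9.0


def test_no_enrichment_is_symmetric():
    cfg = SimulationConfig(
        seed=11, n_chromosomes=2, chrom_length_bp=5_000_000, n_snps_per_chrom=2_500,
        n_genes=12, n_causal_genes_per_trait=6, min_causal_gene_spacing_bp=800_000,
        n_causal_snps_per_gene=8, enrichment_odds=1.0, n_haplotypes=80,
    )
    panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, panel)
    truth = make_truth(cfg, panel, genes, links)
    tracks = generate_feature_tracks(panel, truth, cfg)
    causal = truth.all_causal_snp_ids
    n_tracks = len(tracks)
    hits_causal = hits_null = 0
    for tr in tracks:
        for sid, chrom, pos in zip(panel.snp_ids, panel.chroms, panel.positions):
            if tr.covers(chrom, int(pos) - 1):
                if sid in causal:
                    hits_causal += 1
                else:
                    hits_null += 1
    f_causal = hits_causal / (len(causal) * n_tracks)
    f_null = hits_null / ((panel.n_snps - len(causal)) * n_tracks)
    se = np.sqrt(f_null * (1 - f_null) / (len(causal) * n_tracks))
    assert abs(f_causal - f_null) < 4 * se


def test_tracks_generated_even_with_empty_causal_set():
    cfg = _null_config(seed=4, n_snps=2_000)
    panel = generate_genotype_panel(cfg)
    genes, links = generate_gene_models(cfg, panel)
    truth = make_truth(cfg, panel, genes, links)
    tracks = generate_feature_tracks(panel, truth, cfg)
    assert len(tracks) == len(cfg.feature_categories) * cfg.n_tracks_per_category
    hits = sum(
        tr.covers(c, int(p) - 1)
        for tr in tracks
        for c, p in zip(panel.chroms, panel.positions)
    )
    rate = hits / (panel.n_snps * len(tracks))
    assert rate == pytest.approx(cfg.background_overlap_rate, abs=0.02)


def test_single_gene_and_determinism():
    cfg = SimulationConfig(
        seed=6, n_chromosomes=1, chrom_length_bp=1_000_000, n_snps_per_chrom=300,
        n_genes=1, n_causal_genes_per_trait=1, min_causal_gene_spacing_bp=100_000,
        n_haplotypes=40,
    )
    panel = generate_genotype_panel(cfg)
    genes1, links1 = generate_gene_models(cfg, panel)
    genes2, _ = generate_gene_models(cfg, panel)
    assert len(genes1) == 1
    assert 1 <= genes1[0].start <= genes1[0].end <= cfg.chrom_length_bp
    assert genes1 == genes2


def test_chromosome_too_short_to_place_genes():
    cfg = SimulationConfig(
        seed=6, n_chromosomes=1, chrom_length_bp=200_000, n_snps_per_chrom=50,
        n_genes=4, n_causal_genes_per_trait=1, n_haplotypes=40,
    )
    panel = generate_genotype_panel(cfg)
    with pytest.raises(ValueError, match="too short"):
        generate_gene_models(cfg, panel)


def test_truth_invariants_and_gene_assignment_oracle(default_dataset):
    """Every planted causal SNP maps back to its causal gene through the
    gene-assignment module, and shared genes are the per-trait intersection."""
    ds = default_dataset
    truth = ds.truth
    assert truth.shared_gene_ids == (
        truth.causal_gene_ids["trait1"] & truth.causal_gene_ids["trait2"]
    )
    snp_by_id = {
        sid: (chrom, int(pos))
        for sid, chrom, pos in zip(ds.panel.snp_ids, ds.panel.chroms, ds.panel.positions)
    }
    from snpfunnel.gwas import SnpRecord

    for sid, gene_id in truth.snp_gene.items():
        chrom, pos = snp_by_id[sid]
        a = assign_genes(SnpRecord(sid, chrom, pos, 1e-6), ds.genes, ds.links)
        assert gene_id in a.genes(), f"{sid} not assigned to {gene_id}"


def test_dataset_determinism_and_writers(tmp_path, tiny_config):
    ds1 = simulate_dataset(tiny_config)
    ds2 = simulate_dataset(tiny_config)
    assert np.array_equal(ds1.panel.haplotypes, ds2.panel.haplotypes)
    for t in ds1.stats:
        assert ds1.stats[t].df.equals(ds2.stats[t].df)
    assert [tr.intervals for tr in ds1.tracks] == [tr.intervals for tr in ds2.tracks]
    assert ds1.truth.shared_gene_ids == ds2.truth.shared_gene_ids

    paths = write_dataset(ds1, tmp_path / "out")
    for key in ("track_manifest", "genes", "links", "panel", "truth"):
        assert (key in paths) and open(paths[key]).read(16)
    with open(paths["truth"]) as fh:
        truth_json = json.load(fh)
    assert set(truth_json["shared_gene_ids"]) == ds1.truth.shared_gene_ids
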