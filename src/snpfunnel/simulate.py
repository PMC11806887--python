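"""Synthetic two-trait GWAS benchmark with a known truth manifest.

The generator emulates the statistical structure the prioritizer is built
for, at desk scale:

* an LD-structured phased haplotype panel — within blocks of fixed genomic
  length, each SNP's haplotype column copies the previous column and mutates
  a small fraction of entries, producing high adjacent r² that decays with
  distance; columns are independent across block boundaries;
* non-overlapping gene models with strand and TSS, plus enhancer-to-gene
  link intervals;
* per-trait causal genes with a controlled shared fraction, stratified over
  chromosomes (so chromosome-holdout evaluation is well defined) and spaced
  apart within a chromosome (so association blocks of different causal genes
  do not collide); each causal gene carries a cluster of causal SNPs drawn
  from one LD block of its body, emulating a regulatory causal locus in
  strong mutual LD;
* summary statistics where null SNPs draw p ~ Uniform(0,1) and causal SNPs
  (plus panel partners in strong LD with them) draw p from a Beta
  distribution concentrated near zero;
* binary epigenomic interval tracks in four categories whose odds of
  covering a causal SNP exceed the background odds by a configurable factor.

All randomness flows from one seed through named child streams (``panel``,
``genes``, ``truth``, ``stats-<trait>``, ``tracks``), so any stage can be
regenerated independently and byte-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .features import CATEGORIES, FeatureTrack, write_track
from .genes import EnhancerLink, GeneModel, write_enhancer_links, write_gff3
from .gwas import SummaryStatsTable, _sort, write_summary_stats
from .ld import GenotypePanel, _ld_from_vectors, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "SyntheticDataset",
    "generate_genotype_panel",
    "generate_gene_models",
    "make_truth",
    "generate_summary_stats",
    "generate_feature_tracks",
    "simulate_dataset",
    "write_dataset",
    "TRAITS",
]

TRAITS = ("trait1", "trait2")

import pandas as pd


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark (defaults are the
    package's reference configuration; see docs/methods.md)."""

    seed: int = 7
    n_chromosomes: int = 6
    chrom_length_bp: int = 7_000_000
    n_snps_per_chrom: int = 2_000
    ld_block_len_bp: int = 100_000
    mutation_rate: float = 0.004
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 60
    n_causal_genes_per_trait: int = 18
    shared_causal_fraction: float = 0.5
    min_causal_gene_spacing_bp: int = 1_300_000
    n_causal_snps_per_gene: int = 5
    causal_p_beta_params: tuple[float, float] = (0.1, 20.0)
    feature_categories: tuple[str, ...] = CATEGORIES
    n_tracks_per_category: int = 8
    background_overlap_rate: float = 0.15
    activity_rate: float = 0.1
    active_overlap_rate: float = 0.5
    activity_categories: tuple[str, ...] = ("DHS", "histone")
    enrichment_odds: float = 9.0
    n_haplotypes: int = 200
    gene_length_range: tuple[int, int] = (40_000, 80_000)
    partner_r2: float = 0.8

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_snps_per_chrom": self.n_snps_per_chrom,
            "ld_block_len_bp": self.ld_block_len_bp,
            "n_genes": self.n_genes,
            "n_tracks_per_category": self.n_tracks_per_category,
            "n_haplotypes": self.n_haplotypes,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_causal_genes_per_trait > self.n_genes:
            raise ValueError("n_causal_genes_per_trait cannot exceed n_genes")
        if not (0 <= self.shared_causal_fraction <= 1):
            raise ValueError("shared_causal_fraction must lie in [0, 1]")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment_odds must be positive")
        a, b = self.causal_p_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("causal_p_beta_params must be positive")
        if self.n_snps_per_chrom > self.chrom_length_bp:
            raise ValueError("more SNPs than base pairs on a chromosome")

    @property
    def n_shared_causal(self) -> int:
        # round half up to an integer count of shared genes
        import math

        return int(math.floor(self.shared_causal_fraction * self.n_causal_genes_per_trait + 0.5))


@dataclass
class TruthManifest:
    """Ground truth of one simulation: causal genes/SNPs per trait."""

    causal_gene_ids: dict  # trait -> set[str]
    shared_gene_ids: set
    causal_snp_ids: dict  # trait -> set[str]
    snp_gene: dict  # causal snp id -> its causal gene id

    @property
    def all_causal_snp_ids(self) -> set:
        out: set = set()
        for s in self.causal_snp_ids.values():
            out |= s
        return out

    def is_causal(self, snp_id: str) -> bool:
        return snp_id in self.all_causal_snp_ids

    def to_json(self, path) -> None:
        payload = {
            "causal_gene_ids": {t: sorted(v) for t, v in self.causal_gene_ids.items()},
            "shared_gene_ids": sorted(self.shared_gene_ids),
            "causal_snp_ids": {t: sorted(v) for t, v in self.causal_snp_ids.items()},
            "snp_gene": dict(sorted(self.snp_gene.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            causal_gene_ids={t: set(v) for t, v in d["causal_gene_ids"].items()},
            shared_gene_ids=set(d["shared_gene_ids"]),
            causal_snp_ids={t: set(v) for t, v in d["causal_snp_ids"].items()},
            snp_gene=d["snp_gene"],
        )


# ------------------------------------------------------------- panel


def generate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Simulate the phased haplotype panel (copy-with-mutation LD chains).

    Every SNP's minor-allele frequency is forced into ``maf_range`` by
    rejection resampling of its haplotype column.
    """
    if config.n_haplotypes < 4:
        raise ValueError("panel too small for LD estimation")
    rng = child_rng(config.seed, "panel")
    H = config.n_haplotypes
    lo, hi = config.maf_range
    # target frequencies keep a margin above the lower bound so rejection is cheap
    t_lo = min(lo + 0.03, hi)

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(rng.choice(config.chrom_length_bp, size=config.n_snps_per_chrom, replace=False)) + 1
        block = (pos - 1) // config.ld_block_len_bp
        prev: np.ndarray | None = None
        for j in range(config.n_snps_per_chrom):
            target = rng.uniform(t_lo, hi)
            chained = j > 0 and block[j] == block[j - 1]
            col = None
            for _ in range(60):
                if chained:
                    cand = prev.copy()
                    mut = rng.random(H) < config.mutation_rate
                    if mut.any():
                        cand[mut] = rng.random(int(mut.sum())) < target
                else:
                    cand = (rng.random(H) < target).astype(np.int8)
                f = cand.mean()
                if lo <= min(f, 1 - f) <= hi:
                    col = cand.astype(np.int8)
                    break
            while col is None:  # fall back to i.i.d. draws (loses LD for this SNP)
                cand = (rng.random(H) < target).astype(np.int8)
                f = cand.mean()
                if lo <= min(f, 1 - f) <= hi:
                    col = cand
            columns.append(col)
            prev = col
            snp_ids.append(f"snp_{c}_{j + 1}")
            chroms.append(str(c))
            positions.append(int(pos[j]))
    return GenotypePanel(
        snp_ids=snp_ids,
        chroms=chroms,
        positions=np.array(positions, dtype=np.int64),
        haplotypes=np.column_stack(columns),
    )


# ------------------------------------------------------------- genes


def generate_gene_models(
    config: SimulationConfig, panel: GenotypePanel
) -> tuple[list[GeneModel], list[EnhancerLink]]:
    """Place non-overlapping gene bodies over the SNP landscape (slot per
    gene, random offset, retried so a body contains panel SNPs) and give each
    gene up to two enhancer link intervals nearby."""
    rng = child_rng(config.seed, "genes")
    g_lo, g_hi = config.gene_length_range
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    pos_by_chrom = {
        str(c): np.array(
            [p for p, ch in zip(panel.positions, panel.chroms) if ch == str(c)], dtype=np.int64
        )
        for c in range(1, config.n_chromosomes + 1)
    }

    genes: list[GeneModel] = []
    links: list[EnhancerLink] = []
    gid = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        g = per_chrom[c - 1]
        if g == 0:
            continue
        slot = config.chrom_length_bp // g
        if slot <= g_hi + 2:
            raise ValueError(
                f"chromosome too short to place {g} genes of up to {g_hi} bp"
            )
        snp_pos = pos_by_chrom[chrom]
        for i in range(g):
            gid += 1
            length = int(rng.integers(g_lo, g_hi + 1))
            # near-centred in the slot (small jitter): keeps inter-gene
            # distances close to the slot pitch, so spacing constraints on
            # causal-gene choices behave predictably
            centre = slot * i + (slot - length) // 2
            jitter_max = min(30_000, max((slot - length) // 2 - 1, 1))
            best = None
            for _ in range(30):
                start = int(centre + rng.integers(-jitter_max, jitter_max + 1))
                start = max(1, min(start, slot * (i + 1) - length - 1))
                end = start + length - 1
                n_in = int(np.searchsorted(snp_pos, end, "right") - np.searchsorted(snp_pos, start, "left"))
                if best is None or n_in > best[2]:
                    best = (start, end, n_in)
                if n_in >= 2:
                    break
            start, end, _ = best
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(gene_id=f"g{gid}", chrom=chrom, strand=strand, start=start, end=end)
            genes.append(gene)
            for _ in range(int(rng.integers(0, 3))):
                off = int(rng.integers(10_000, 150_000))
                elen = 2_000
                if rng.random() < 0.5:
                    s0 = gene.end + off
                else:
                    s0 = gene.start - 1 - off - elen
                s0 = max(0, min(s0, config.chrom_length_bp - elen))
                links.append(EnhancerLink(chrom=chrom, start=s0, end=s0 + elen, gene_id=gene.gene_id))
    return genes, links


# ------------------------------------------------------------- truth


def make_truth(
    config: SimulationConfig,
    panel: GenotypePanel,
    genes: list[GeneModel],
    links: list[EnhancerLink],
) -> TruthManifest:
    """Choose causal genes (shared fraction rounded half up; stratified over
    chromosomes; spaced within a chromosome) and, for each, a cluster of
    causal SNPs from the single LD block holding most of its body SNPs."""
    rng = child_rng(config.seed, "truth")
    n_causal = config.n_causal_genes_per_trait
    n_shared = config.n_shared_causal

    if n_causal == 0:
        return TruthManifest(
            causal_gene_ids={t: set() for t in TRAITS},
            shared_gene_ids=set(),
            causal_snp_ids={t: set() for t in TRAITS},
            snp_gene={},
        )

    pos = panel.positions
    chrom_arr = np.array(panel.chroms)
    body_snps: dict[str, list[int]] = {}
    for g in genes:
        on = np.where((chrom_arr == g.chrom) & (pos >= g.start) & (pos <= g.end))[0]
        body_snps[g.gene_id] = on.tolist()
    eligible = [g for g in genes if len(body_snps[g.gene_id]) >= 2]

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in eligible:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: g.start)
    chrom_order = sorted(by_chrom)
    chrom_order = [chrom_order[i] for i in rng.permutation(len(chrom_order))]

    n_union = n_shared + 2 * (n_causal - n_shared)
    spacing = config.min_causal_gene_spacing_bp
    mid = lambda g: (g.start + g.end) // 2

    # per chromosome, the maximal left-to-right chain of genes pairwise at
    # least `spacing` apart; any subset of it keeps the spacing guarantee
    chains: dict[str, list[GeneModel]] = {}
    for c, gene_list in by_chrom.items():
        chain: list[GeneModel] = []
        for g in gene_list:
            if not chain or mid(g) - mid(chain[-1]) >= spacing:
                chain.append(g)
        chains[c] = chain

    # distribute the union of causal loci over chromosomes as evenly as the
    # chains allow (chromosomes receiving the remainder are random)
    quota = {c: 0 for c in chrom_order}
    remaining = n_union
    ci = 0
    stalled = 0
    while remaining > 0 and stalled < len(chrom_order):
        c = chrom_order[ci % len(chrom_order)]
        ci += 1
        if quota[c] < len(chains[c]):
            quota[c] += 1
            remaining -= 1
            stalled = 0
        else:
            stalled += 1
    if remaining > 0:
        raise ValueError(
            "not enough well-separated SNP-bearing genes to place "
            f"{n_union} causal loci (spacing {spacing} bp)"
        )

    # evenly spread each chromosome's quota along its chain, then assign loci
    # to the shared / trait-specific groups round-robin across chromosomes
    per_chrom_loci: dict[str, list[GeneModel]] = {}
    for c in chrom_order:
        k, chain = quota[c], chains[c]
        if k == 0:
            per_chrom_loci[c] = []
        elif k == 1:
            per_chrom_loci[c] = [chain[len(chain) // 2]]
        else:
            idx = np.unique(np.round(np.linspace(0, len(chain) - 1, k)).astype(int))
            per_chrom_loci[c] = [chain[i] for i in idx]
        order = rng.permutation(len(per_chrom_loci[c]))
        per_chrom_loci[c] = [per_chrom_loci[c][i] for i in order]

    interleaved: list[GeneModel] = []
    ci = 0
    while any(per_chrom_loci.values()):
        c = chrom_order[ci % len(chrom_order)]
        ci += 1
        if per_chrom_loci[c]:
            interleaved.append(per_chrom_loci[c].pop())
    shared = interleaved[:n_shared]
    spec1 = interleaved[n_shared : n_causal]
    spec2 = interleaved[n_causal : n_union]

    block_len = config.ld_block_len_bp
    snp_gene: dict[str, str] = {}

    def causal_snps_of(g: GeneModel) -> list[str]:
        idxs = body_snps[g.gene_id]
        blocks: dict[int, list[int]] = {}
        for i in idxs:
            blocks.setdefault(int((pos[i] - 1) // block_len), []).append(i)
        best = max(blocks.values(), key=len)
        best = sorted(best, key=lambda i: pos[i])
        k = config.n_causal_snps_per_gene
        if len(best) > k:
            start = int(rng.integers(0, len(best) - k + 1))
            best = best[start : start + k]
        return [panel.snp_ids[i] for i in best]

    causal_gene_ids = {
        TRAITS[0]: {g.gene_id for g in shared + spec1},
        TRAITS[1]: {g.gene_id for g in shared + spec2},
    }
    causal_snp_ids: dict[str, set] = {t: set() for t in TRAITS}
    for g in shared + spec1 + spec2:
        snps = causal_snps_of(g)
        for s in snps:
            snp_gene[s] = g.gene_id
        for t in TRAITS:
            if g.gene_id in causal_gene_ids[t]:
                causal_snp_ids[t].update(snps)

    return TruthManifest(
        causal_gene_ids=causal_gene_ids,
        shared_gene_ids={g.gene_id for g in shared},
        causal_snp_ids=causal_snp_ids,
        snp_gene=snp_gene,
    )


# ------------------------------------------------------------- stats


def _signal_indices(panel: GenotypePanel, causal_idx: list[int], config: SimulationConfig) -> np.ndarray:
    """Causal SNPs plus same-LD-block panel partners with r² >= partner_r2."""
    signal = set(causal_idx)
    block_len = config.ld_block_len_bp
    pos = panel.positions
    chrom_arr = np.array(panel.chroms)
    key = lambda i: (panel.chroms[i], int((pos[i] - 1) // block_len))
    causal_by_block: dict[tuple, list[int]] = {}
    for i in causal_idx:
        causal_by_block.setdefault(key(i), []).append(i)
    for (chrom, blk), cidx in causal_by_block.items():
        members = np.where(
            (chrom_arr == chrom) & ((pos - 1) // block_len == blk)
        )[0]
        for j in members:
            if j in signal:
                continue
            b = panel.haplotypes[:, j].astype(np.int64)
            for i in cidx:
                a = panel.haplotypes[:, i].astype(np.int64)
                try:
                    r2, _ = _ld_from_vectors(a, b)
                except ValueError:
                    continue
                if r2 >= config.partner_r2:
                    signal.add(int(j))
                    break
    return np.array(sorted(signal), dtype=int)


def generate_summary_stats(
    panel: GenotypePanel, truth: TruthManifest, trait: str, config: SimulationConfig
) -> SummaryStatsTable:
    """Per-SNP p-values for one trait: Uniform(0,1) nulls; Beta-distributed
    (concentrated near 0) for causal SNPs and their strong-LD panel partners.

    With an empty causal set the output equals a pure uniform generator run
    on the same stream.
    """
    if trait not in truth.causal_snp_ids:
        raise ValueError(f"unknown trait {trait!r}; known: {sorted(truth.causal_snp_ids)}")
    rng = child_rng(config.seed, f"stats-{trait}")
    n = panel.n_snps
    tiny = np.finfo(float).tiny
    p = np.clip(rng.random(n), tiny, 1.0)
    causal_idx = [panel.index_of(s) for s in truth.causal_snp_ids[trait]]
    if causal_idx:
        signal = _signal_indices(panel, causal_idx, config)
        a, b = config.causal_p_beta_params
        p[signal] = np.clip(rng.beta(a, b, size=len(signal)), tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": panel.chroms,
            "pos": panel.positions,
            "pvalue": p,
        }
    )
    return SummaryStatsTable(_sort(df), trait=trait, provenance=f"simulated (seed={config.seed})")


# ------------------------------------------------------------- tracks


def generate_feature_tracks(
    panel: GenotypePanel, truth: TruthManifest, config: SimulationConfig
) -> list[FeatureTrack]:
    """Interval tracks per category whose odds of covering a causal SNP are
    ``enrichment_odds`` times the background odds.

    Null-SNP annotations in the ``activity_categories`` (by default the
    generic regulatory ones: open chromatin and histone marks) are correlated
    across tracks, as real annotations are: a latent per-SNP activity state
    ("regulatory element here") is drawn once with probability
    ``activity_rate``, and those tracks cover active SNPs at
    ``active_overlap_rate`` and inactive SNPs at a compensating low rate, so
    the *marginal* per-track overlap rate of null SNPs is exactly
    ``background_overlap_rate`` in every category. Causal SNPs draw every
    track independently at the enriched rate implied by ``enrichment_odds``
    (with enrichment_odds = 1 their marginal rate equals the background).
    Thus every per-track causal-vs-null odds ratio is ``enrichment_odds``,
    while causal rows are the only rows dense across *all four* categories —
    a background regulatory element is dense only in the activity-coupled
    ones. Intervals are short (150-300 bp) windows containing the SNP, so
    neighbors are essentially never swept in at the default SNP spacing.
    """
    rng = child_rng(config.seed, "tracks")
    p0 = config.background_overlap_rate
    o0 = p0 / (1 - p0)
    p1 = config.enrichment_odds * o0 / (1 + config.enrichment_odds * o0)
    p_hi = config.active_overlap_rate
    q = config.activity_rate
    if not (0 <= q < 1) or not (0 < p_hi <= 1):
        raise ValueError("activity_rate must lie in [0,1) and active_overlap_rate in (0,1]")
    p_lo = (p0 - q * p_hi) / (1 - q)
    if p_lo < 0:
        raise ValueError("activity_rate * active_overlap_rate exceeds background_overlap_rate")
    causal = truth.all_causal_snp_ids
    is_causal = np.array([s in causal for s in panel.snp_ids])
    active = rng.random(panel.n_snps) < config.activity_rate
    L = config.chrom_length_bp

    tracks: list[FeatureTrack] = []
    for cat in config.feature_categories:
        if cat in config.activity_categories:
            null_probs = np.where(active, p_hi, p_lo)
        else:
            null_probs = np.full(panel.n_snps, p0)
        probs = np.where(is_causal, p1, null_probs)
        for t in range(config.n_tracks_per_category):
            hit = rng.random(panel.n_snps) < probs
            intervals: list[tuple[str, int, int]] = []
            for i in np.where(hit)[0]:
                pos0 = int(panel.positions[i]) - 1
                width = int(rng.integers(150, 301))
                start = pos0 - int(rng.integers(0, width))
                start = max(start, pos0 - width + 1, 0)
                start = min(start, pos0, max(L - width, 0))
                intervals.append((panel.chroms[i], start, start + width))
            tracks.append(FeatureTrack(name=f"{cat}_{t + 1}", category=cat, intervals=intervals))
    return tracks


# ------------------------------------------------------------- orchestration


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    panel: GenotypePanel
    genes: list[GeneModel]
    links: list[EnhancerLink]
    truth: TruthManifest
    stats: dict  # trait -> SummaryStatsTable
    tracks: list[FeatureTrack]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full two-trait benchmark from one config."""
    panel = generate_genotype_panel(config)
    genes, links = generate_gene_models(config, panel)
    truth = make_truth(config, panel, genes, links)
    stats = {t: generate_summary_stats(panel, truth, t, config) for t in TRAITS}
    tracks = generate_feature_tracks(panel, truth, config)
    return SyntheticDataset(
        config=config, panel=panel, genes=genes, links=links, truth=truth, stats=stats, tracks=tracks
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every component in its interchange format; returns the path map
    a PipelineConfig needs (summary stats TSV, track manifest + BEDs, GFF3
    genes, BED enhancer links, phased VCF panel, JSON truth)."""
    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
    paths: dict = {"sumstats": {}}
    for t, table in ds.stats.items():
        p = os.path.join(outdir, f"{t}.sumstats.tsv")
        write_summary_stats(table, p)
        paths["sumstats"][t] = p
    manifest = os.path.join(outdir, "track_manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("name\tcategory\tpath\n")
        for tr in ds.tracks:
            rel = os.path.join("tracks", f"{tr.name}.bed")
            write_track(tr, os.path.join(outdir, rel))
            fh.write(f"{tr.name}\t{tr.category}\t{rel}\n")
    paths["track_manifest"] = manifest
    paths["genes"] = os.path.join(outdir, "genes.gff3")
    write_gff3(ds.genes, paths["genes"])
    paths["links"] = os.path.join(outdir, "enhancers.bed")
    write_enhancer_links(ds.links, paths["links"])
    paths["panel"] = os.path.join(outdir, "panel.vcf")
    write_vcf(ds.panel, paths["panel"])
    paths["truth"] = os.path.join(outdir, "truth.json")
    ds.truth.to_json(paths["truth"])
    return paths
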