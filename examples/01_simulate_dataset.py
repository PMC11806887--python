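"""Generate a synthetic two-trait GWAS benchmark and inspect its truth.

The generator produces everything the prioritization funnel consumes —
summary statistics for two traits with partially shared causal genes, a
phased LD-structured haplotype panel, epigenomic interval tracks enriched at
causal SNPs, gene models and enhancer links — plus a truth manifest naming
the planted causal genes and SNPs.
"""

import tempfile

from snpfunnel import SimulationConfig, simulate_dataset
from snpfunnel.simulate import write_dataset

config = SimulationConfig(seed=7)
ds = simulate_dataset(config)

print(f"chromosomes      : {config.n_chromosomes} x {config.chrom_length_bp/1e6:.0f} Mb")
print(f"panel            : {ds.panel.n_haplotypes} haplotypes x {ds.panel.n_snps} SNPs")
print(f"genes / enhancers: {len(ds.genes)} / {len(ds.links)}")
print(f"feature tracks   : {len(ds.tracks)} ({config.n_tracks_per_category} per category)")
for trait, table in ds.stats.items():
    causal = ds.truth.causal_snp_ids[trait]
    print(f"{trait}: {len(table)} SNP records, {len(causal)} planted causal SNPs "
          f"in {len(ds.truth.causal_gene_ids[trait])} causal genes")
print(f"shared causal genes: {sorted(ds.truth.shared_gene_ids)}")

with tempfile.TemporaryDirectory() as d:
    paths = write_dataset(ds, d)
    print("\nfiles written:", ", ".join(sorted(k for k in paths if k != "sumstats")),
          "+ per-trait summary stats")

# The shared causal genes above are the ground truth the cross-trait funnel
# is expected to recover; everything else is realistic background noise.
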