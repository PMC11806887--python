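"""Linkage disequilibrium from a phased haplotype panel, shared-gene
intersection, and the cross-trait LD-sharing filter.

LD between two biallelic sites is measured on phased haplotypes: r² is the
squared Pearson correlation of the two allele-indicator vectors, and
D' = |D| / D_max with D = p_AB - p_A p_B and D_max the classical bound given
the marginal allele frequencies. The cross-trait filter keeps a trait-1
candidate SNP when one of its target genes is shared with trait 2 and some
trait-2 candidate linked to a shared gene lies in strong LD with it
(r² at or above the threshold; a SNP is trivially in LD with itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneAssignment
from .gwas import normalize_chrom
from .model import SnpScore

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "LdResult",
    "FinalCandidateSet",
    "compute_r2",
    "shared_genes",
    "filter_by_ld",
    "write_vcf",
    "read_vcf",
    "write_final_set",
    "DEFAULT_R2_THRESHOLD",
]

#: conventional strong-LD cut on r²
DEFAULT_R2_THRESHOLD = 0.8


@dataclass
class GenotypePanel:
    """Phased reference panel: ``haplotypes`` is n_haplotypes x n_snps with
    0/1 allele indicators; SNP ids are unique."""

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # (n_snps,) int64, 1-based
    haplotypes: np.ndarray  # (n_haplotypes, n_snps) int8
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] < 4:
            raise ValueError("panel too small for LD estimation")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in panel")
        if not self._index:
            self._index.update({s: i for i, s in enumerate(self.snp_ids)})

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} absent from panel") from None


@dataclass(frozen=True)
class LdResult:
    snp_a: str
    snp_b: str
    r2: float
    d_prime: float


@dataclass
class FinalCandidateSet:
    """Trait-1 candidates surviving the cross-trait LD-sharing filter."""

    trait: str
    snps: list[SnpScore]
    genes: set[str]
    supporting_pairs: list[tuple[str, str, float, str]]  # (snp1, snp2, r2, shared gene)


def _ld_from_vectors(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pa, pb = float(a.mean()), float(b.mean())
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD undefined for monomorphic site")
    pab = float((a & b).mean())
    d = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    return r2, d_prime


def compute_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> LdResult:
    """Pairwise LD of two panel SNPs (r² and D'); symmetric in its arguments.

    Raises ``ValueError`` for a monomorphic site and ``KeyError`` for a SNP
    absent from the panel.
    """
    ia, ib = panel.index_of(snp_a), panel.index_of(snp_b)
    a = panel.haplotypes[:, ia].astype(np.int64)
    b = panel.haplotypes[:, ib].astype(np.int64)
    r2, d_prime = _ld_from_vectors(a, b)
    return LdResult(snp_a=snp_a, snp_b=snp_b, r2=r2, d_prime=d_prime)


def shared_genes(
    assign1: list[GeneAssignment], assign2: list[GeneAssignment]
) -> set[str]:
    """Genes targeted by candidates of both traits: the intersection of each
    trait's union of assigned genes."""
    g1 = set().union(*(a.genes() for a in assign1)) if assign1 else set()
    g2 = set().union(*(a.genes() for a in assign2)) if assign2 else set()
    return g1 & g2


def filter_by_ld(
    cands1: list[SnpScore],
    cands2: list[SnpScore],
    shared: set[str],
    assign1: list[GeneAssignment],
    assign2: list[GeneAssignment],
    panel: GenotypePanel,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> FinalCandidateSet:
    """Cross-trait LD-sharing filter on trait-1 candidates.

    A trait-1 candidate survives iff (i) one of its assigned genes is in
    ``shared`` and (ii) some trait-2 candidate assigned to a shared gene has
    pairwise r² >= ``r2_threshold`` with it (identical SNP ids count as
    r² = 1; SNPs on different chromosomes have r² = 0 by definition). A
    candidate missing from the panel is excluded with a logged warning.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    a1 = {a.snp_id: a for a in assign1}
    a2 = {a.snp_id: a for a in assign2}
    trait = cands1[0].trait if cands1 else "trait1"

    partners = []  # trait-2 candidates linked to a shared gene
    for c in cands2:
        genes2 = a2.get(c.snp_id, GeneAssignment(c.snp_id, frozenset())).genes() & shared
        if genes2:
            partners.append((c, genes2))

    kept: list[SnpScore] = []
    genes_out: set[str] = set()
    pairs: list[tuple[str, str, float, str]] = []
    for c in cands1:
        my_shared = a1.get(c.snp_id, GeneAssignment(c.snp_id, frozenset())).genes() & shared
        if not my_shared:
            continue
        support: list[tuple[str, str, float, str]] = []
        for p, genes2 in partners:
            if p.snp_id == c.snp_id:
                r2 = 1.0
            else:
                try:
                    ia, ib = panel.index_of(c.snp_id), panel.index_of(p.snp_id)
                except KeyError as err:
                    missing = c.snp_id if c.snp_id not in panel._index else p.snp_id
                    logger.warning("candidate %s absent from panel; pair skipped (%s)", missing, err)
                    continue
                if panel.chroms[ia] != panel.chroms[ib]:
                    r2 = 0.0
                else:
                    try:
                        r2 = compute_r2(panel, c.snp_id, p.snp_id).r2
                    except ValueError:
                        logger.warning(
                            "monomorphic pair (%s, %s) skipped in LD filter", c.snp_id, p.snp_id
                        )
                        continue
            if r2 >= r2_threshold:
                common = sorted(my_shared & genes2) or sorted(my_shared)
                support.append((c.snp_id, p.snp_id, r2, common[0]))
        if support:
            kept.append(c)
            genes_out |= my_shared
            pairs.extend(support)
    return FinalCandidateSet(trait=trait, snps=kept, genes=genes_out, supporting_pairs=pairs)


# ---------------------------------------------------------------- file I/O


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with phased GT fields; haplotypes 2i and 2i+1 form
    sample i, so the panel must hold an even haplotype count."""
    H = panel.n_haplotypes
    if H % 2:
        raise ValueError("VCF export needs an even number of haplotypes")
    n_samples = H // 2
    samples = [f"S{i + 1}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(panel.chroms), key=lambda s: (len(s), s)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = sorted(
            range(panel.n_snps), key=lambda i: ((len(panel.chroms[i]), panel.chroms[i]), int(panel.positions[i]))
        )
        for i in order:
            gts = "\t".join(
                f"{panel.haplotypes[2 * s, i]}|{panel.haplotypes[2 * s + 1, i]}"
                for s in range(n_samples)
            )
            fh.write(
                f"{panel.chroms[i]}\t{panel.positions[i]}\t{panel.snp_ids[i]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypePanel:
    """Load a phased panel VCF; unphased genotypes are rejected (phasing is
    required for exact haplotype LD, and EM phasing is out of scope)."""
    from cyvcf2 import VCF

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    vcf = VCF(str(path))
    for var in vcf:
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] < 3 or not bool(np.all(gts[:, 2] == 1)):
            raise ValueError(f"unphased genotype at {var.ID or var.POS}; phased GT required")
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(normalize_chrom(var.CHROM))
        positions.append(var.POS)
        columns.append(hap)
    return GenotypePanel(
        snp_ids=snp_ids,
        chroms=chroms,
        positions=np.array(positions, dtype=np.int64),
        haplotypes=np.column_stack(columns),
    )


def write_final_set(final: FinalCandidateSet, path) -> None:
    by_snp: dict[str, list[tuple[str, str, float, str]]] = {}
    for pair in final.supporting_pairs:
        by_snp.setdefault(pair[0], []).append(pair)
    with open(path, "w") as fh:
        fh.write("snp_id\tgene_id\tpartner_snp\tr2\ttrait\n")
        for s in final.snps:
            for snp1, snp2, r2, gene in sorted(by_snp.get(s.snp_id, [])):
                fh.write(f"{snp1}\t{gene}\t{snp2}\t{r2:.6f}\t{final.trait}\n")
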