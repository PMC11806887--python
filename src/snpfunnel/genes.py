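"""SNP-to-target-gene assignment.

A candidate SNP is linked to a gene by three evidence classes:

* ``body`` — the SNP falls inside the gene body (1-based inclusive bounds);
* ``promoter`` — the SNP lies in the strand-aware window covering the 3 kb
  immediately upstream of the transcription start site (half-open: the TSS
  base itself belongs to the body, not the promoter);
* ``enhancer`` — the SNP falls inside a precomputed enhancer interval whose
  target gene is given by the link table (enhancer-gene calling is upstream
  of this package).

A SNP may collect several genes and several evidence classes; no class
outranks another.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .gwas import SnpRecord, normalize_chrom

__all__ = [
    "GeneModel",
    "EnhancerLink",
    "GeneAssignment",
    "GeneIndex",
    "assign_genes",
    "read_gene_models",
    "read_enhancer_links",
    "write_gff3",
    "write_enhancer_links",
    "write_assignments",
    "DEFAULT_PROMOTER_KB",
]

DEFAULT_PROMOTER_KB = 3.0


@dataclass(frozen=True)
class GeneModel:
    """Gene body bounds are 1-based inclusive; TSS sits at ``start`` on the
    plus strand and at ``end`` on the minus strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class EnhancerLink:
    """An enhancer interval (0-based half-open) linked to a target gene."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"enhancer link {self.gene_id}: need 0 <= start < end")


@dataclass(frozen=True)
class GeneAssignment:
    """All (gene, evidence) links of one SNP; the set may be empty."""

    snp_id: str
    assignments: frozenset  # of (gene_id, evidence)

    def genes(self) -> set[str]:
        return {g for g, _ in self.assignments}


class GeneIndex:
    """Interval indexes over gene bodies, promoter windows and enhancer links
    for one fixed ``promoter_kb``."""

    def __init__(
        self,
        genes: list[GeneModel],
        links: list[EnhancerLink],
        promoter_kb: float = DEFAULT_PROMOTER_KB,
    ):
        if promoter_kb <= 0:
            raise ValueError("promoter_kb must be positive")
        self.promoter_kb = promoter_kb
        w = int(round(promoter_kb * 1000))
        known = {g.gene_id for g in genes}
        for link in links:
            if link.gene_id not in known:
                raise ValueError(f"enhancer link names unknown gene {link.gene_id!r}")

        # trees keyed by chrom, holding 1-based inclusive ranges as [lo, hi+1)
        self._body: dict[str, IntervalTree] = {}
        self._prom: dict[str, IntervalTree] = {}
        self._enh: dict[str, IntervalTree] = {}
        for g in genes:
            c = normalize_chrom(g.chrom)
            self._body.setdefault(c, IntervalTree())[g.start : g.end + 1] = g.gene_id
            if g.strand == "+":
                lo, hi = g.tss - w, g.tss - 1  # [tss-w, tss) in 1-based terms
            else:
                lo, hi = g.tss + 1, g.tss + w  # (tss, tss+w]
            if hi >= lo:
                lo = max(lo, 1)
                self._prom.setdefault(c, IntervalTree())[lo : hi + 1] = g.gene_id
        for link in links:
            c = normalize_chrom(link.chrom)
            # 0-based half-open [start, end) covers 1-based positions start+1..end
            self._enh.setdefault(c, IntervalTree())[link.start + 1 : link.end + 1] = link.gene_id

    def assign(self, snp: SnpRecord) -> GeneAssignment:
        c = normalize_chrom(snp.chrom)
        hits = set()
        for trees, evidence in ((self._body, "body"), (self._prom, "promoter"), (self._enh, "enhancer")):
            tree = trees.get(c)
            if tree is not None:
                for iv in tree.at(snp.pos):
                    hits.add((iv.data, evidence))
        return GeneAssignment(snp_id=snp.snp_id, assignments=frozenset(hits))


def assign_genes(
    snp: SnpRecord,
    genes: list[GeneModel],
    links: list[EnhancerLink],
    promoter_kb: float = DEFAULT_PROMOTER_KB,
) -> GeneAssignment:
    """Assign target genes to one SNP (see module docstring for the rules)."""
    return GeneIndex(genes, links, promoter_kb).assign(snp)


# ---------------------------------------------------------------- file I/O


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from GFF3 (``gene`` features with an ``ID`` attribute,
    1-based inclusive) or 6-column BED (0-based half-open)."""
    spath = str(path)
    if spath.endswith((".bed", ".bed.gz")):
        df = pd.read_csv(spath, sep="\t", header=None, comment="#")
        return [
            GeneModel(
                gene_id=str(r[3]),
                chrom=normalize_chrom(str(r[0])),
                strand=str(r[5]),
                start=int(r[1]) + 1,
                end=int(r[2]),
            )
            for _, r in df.iterrows()
        ]
    import gffutils

    db = gffutils.create_db(
        spath, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    out = []
    for feat in db.features_of_type("gene"):
        out.append(
            GeneModel(
                gene_id=feat.attributes["ID"][0],
                chrom=normalize_chrom(feat.seqid),
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def read_enhancer_links(path, genes: list[GeneModel] | None = None) -> list[EnhancerLink]:
    """Enhancer links from BED plus a 4th gene-id column; if ``genes`` is
    given, a link naming an unknown gene is an error."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    links = [
        EnhancerLink(
            chrom=normalize_chrom(str(r[0])), start=int(r[1]), end=int(r[2]), gene_id=str(r[3])
        )
        for _, r in df.iterrows()
    ]
    if genes is not None:
        known = {g.gene_id for g in genes}
        for link in links:
            if link.gene_id not in known:
                raise ValueError(f"enhancer link names unknown gene {link.gene_id!r}")
    return links


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tsnpfunnel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_enhancer_links(links: list[EnhancerLink], path) -> None:
    with open(path, "w") as fh:
        for link in sorted(links, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{link.chrom}\t{link.start}\t{link.end}\t{link.gene_id}\n")


def write_assignments(assignments: list[GeneAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tgene_id\tevidence\n")
        for a in assignments:
            for gene_id, evidence in sorted(a.assignments):
                fh.write(f"{a.snp_id}\t{gene_id}\t{evidence}\n")
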