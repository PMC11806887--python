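"""Association-block construction from filtered summary statistics.

Blocks are built greedily: the unconsumed SNP with the globally lowest
p-value becomes the next lead unless it sits within the minimum lead
separation (default 1 Mb) of an already chosen lead on the same chromosome,
in which case it is dropped. A block holds its lead plus the 30 most
significant still-free SNPs inside a +/- window around the lead. A SNP
belongs to at most one block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .gwas import SnpRecord, SummaryStatsTable, _chrom_sort_key

__all__ = ["AssociationBlock", "build_blocks", "blocks_to_json", "blocks_to_bed"]

_FREE, _MEMBER, _SKIPPED = 0, 1, 2


@dataclass
class AssociationBlock:
    """A lead SNP plus up to ``n_neighbors`` neighbors; the CNN's unit of labeling."""

    block_id: str
    trait: str
    chrom: str
    lead: SnpRecord
    members: list[SnpRecord]  # position-sorted, includes the lead
    window_bp: int

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.snp_id for m in self.members]


def build_blocks(
    table: SummaryStatsTable,
    min_lead_separation_bp: int = 1_000_000,
    n_neighbors: int = 30,
    window_bp: int = 500_000,
) -> list[AssociationBlock]:
    """Partition a p-value-filtered table into association blocks.

    Ties in p-value are broken by lower position, then lexicographic SNP id,
    making the output a pure function of the input. Blocks are returned
    sorted by (chromosome, lead position) and labelled ``{trait}-blk###``.
    """
    if min_lead_separation_bp <= 0:
        raise ValueError("min_lead_separation_bp must be positive")
    recs = table.records()
    if not recs:
        return []

    order = sorted(range(len(recs)), key=lambda i: (recs[i].pvalue, recs[i].pos, recs[i].snp_id))
    status = [_FREE] * len(recs)
    leads_by_chrom: dict[str, list[int]] = {}
    raw_blocks: list[tuple[SnpRecord, list[SnpRecord]]] = []

    for i in order:
        if status[i] != _FREE:
            continue
        r = recs[i]
        if any(abs(r.pos - lp) < min_lead_separation_bp for lp in leads_by_chrom.get(r.chrom, ())):
            status[i] = _SKIPPED
            continue
        # new lead: gather the n_neighbors most significant free SNPs in window
        status[i] = _MEMBER
        leads_by_chrom.setdefault(r.chrom, []).append(r.pos)
        neigh = [
            j
            for j in range(len(recs))
            if status[j] == _FREE
            and recs[j].chrom == r.chrom
            and abs(recs[j].pos - r.pos) <= window_bp
        ]
        neigh.sort(key=lambda j: (recs[j].pvalue, recs[j].pos, recs[j].snp_id))
        chosen = neigh[:n_neighbors]
        for j in chosen:
            status[j] = _MEMBER
        members = sorted([r] + [recs[j] for j in chosen], key=lambda m: m.pos)
        raw_blocks.append((r, members))

    raw_blocks.sort(key=lambda b: (_chrom_sort_key(b[0].chrom), b[0].pos))
    return [
        AssociationBlock(
            block_id=f"{table.trait}-blk{k + 1:03d}",
            trait=table.trait,
            chrom=lead.chrom,
            lead=lead,
            members=members,
            window_bp=window_bp,
        )
        for k, (lead, members) in enumerate(raw_blocks)
    ]


def blocks_to_json(blocks: list[AssociationBlock], path) -> None:
    payload = [
        {
            "block_id": b.block_id,
            "trait": b.trait,
            "chrom": b.chrom,
            "lead": b.lead.snp_id,
            "window_bp": b.window_bp,
            "members": [
                {"snp_id": m.snp_id, "pos": m.pos, "pvalue": m.pvalue} for m in b.members
            ],
        }
        for b in blocks
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def blocks_to_bed(blocks: list[AssociationBlock], path) -> None:
    """Block footprints as BED (0-based half-open) for inspection."""
    with open(path, "w") as fh:
        for b in blocks:
            start = min(m.pos for m in b.members) - 1
            end = max(m.pos for m in b.members)
            fh.write(f"{b.chrom}\t{start}\t{end}\t{b.block_id}\n")
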