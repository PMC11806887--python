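"""Reading, validation and p-value filtering of GWAS summary statistics.

The pipeline consumes only four columns per SNP — identifier, chromosome,
1-based position and association p-value. Effect sizes, alleles and standard
errors are deliberately out of scope: every downstream stage (block
construction, feature annotation, CNN scoring) is driven by position and
p-value alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "SummaryStatsTable",
    "read_summary_stats",
    "filter_by_pvalue",
    "write_summary_stats",
    "DEFAULT_PVALUE_THRESHOLD",
]

#: SNPs with association p-value above this are discarded before block
#: construction (the conventional suggestive-association cut used by the
#: upstream feature-map CNN approach).
DEFAULT_PVALUE_THRESHOLD = 5e-4

# accepted case-insensitive header synonyms per canonical column
_SYNONYMS = {
    "snp_id": {"snp_id", "snp", "id", "rsid", "marker", "markername"},
    "chrom": {"chrom", "chr", "chromosome"},
    "pos": {"pos", "position", "bp", "base_pair_location"},
    "pvalue": {"pvalue", "pval", "p", "p_value"},
}


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One summary-statistic row: a SNP of one trait."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    pvalue: float
    trait: str = ""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome label."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class SummaryStatsTable:
    """Validated, position-sorted summary statistics for one trait.

    ``df`` holds columns ``snp_id, chrom, pos, pvalue`` sorted by
    (chromosome, position); ``provenance`` records where the rows came from
    and which filters have been applied.
    """

    df: pd.DataFrame
    trait: str
    provenance: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[SnpRecord]:
        return [
            SnpRecord(r.snp_id, r.chrom, int(r.pos), float(r.pvalue), self.trait)
            for r in self.df.itertuples(index=False)
        ]

    @classmethod
    def from_records(
        cls, records: list[SnpRecord], trait: str, provenance: str = ""
    ) -> "SummaryStatsTable":
        df = pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in records],
                "chrom": [str(r.chrom) for r in records],
                "pos": [int(r.pos) for r in records],
                "pvalue": [float(r.pvalue) for r in records],
            }
        )
        return cls(_sort(df), trait=trait, provenance=provenance)


def _sort(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(_chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lowered = {c.lower().strip(): c for c in columns}
    for canonical, names in _SYNONYMS.items():
        hit = next((lowered[n] for n in names if n in lowered), None)
        if hit is None:
            raise ValueError(
                f"missing required column {canonical!r} "
                f"(accepted names: {sorted(names)}; got {columns})"
            )
        mapping[canonical] = hit
    return mapping


def read_summary_stats(path, trait: str) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    The delimiter (tab or comma) is sniffed from the header line; gzip input
    is handled transparently. Rows violating the record invariants
    (``pos >= 1``, ``0 < p <= 1``) are dropped with a logged reason; a
    duplicated SNP id or a mix of ``chr``-prefixed and bare chromosome labels
    is an error.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(list(raw.columns))
    df = pd.DataFrame(
        {
            "snp_id": raw[cols["snp_id"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
            "pvalue": pd.to_numeric(raw[cols["pvalue"]], errors="coerce"),
        }
    )

    prefixed = df["chrom"].str.lower().str.startswith("chr")
    if prefixed.any() and not prefixed.all():
        raise ValueError(
            "mixed chromosome dialects: some labels carry a 'chr' prefix and some do not"
        )
    df["chrom"] = df["chrom"].map(normalize_chrom)

    bad_pos = df["pos"].isna() | (df["pos"] < 1)
    bad_p = df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1)
    n_bad = int((bad_pos | bad_p).sum())
    if n_bad:
        for i in df.index[bad_pos | bad_p]:
            reason = "invalid position" if bad_pos.iat[i] else "p-value outside (0, 1]"
            logger.debug("rejected row %d (%s): %s", i, df["snp_id"].iat[i], reason)
        logger.info("rejected %d malformed row(s) while reading %s", n_bad, path)
        df = df[~(bad_pos | bad_p)]
    df["pos"] = df["pos"].astype(int)

    dup = df["snp_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate snp_id in {path}: {sorted(df['snp_id'][dup].unique())[:5]}"
        )

    return SummaryStatsTable(
        _sort(df), trait=trait, provenance=f"read from {path} ({n_bad} rows rejected)"
    )


def filter_by_pvalue(
    table: SummaryStatsTable, threshold: float = DEFAULT_PVALUE_THRESHOLD
) -> SummaryStatsTable:
    """Keep exactly the records with ``pvalue <= threshold``.

    The comparison is inclusive: a p-value equal to the threshold survives
    (the filter removes strictly larger values). Idempotent by construction.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    kept = table.df[table.df["pvalue"].to_numpy() <= threshold].reset_index(drop=True)
    return SummaryStatsTable(
        kept,
        trait=table.trait,
        provenance=f"{table.provenance}; filtered at p<={threshold:g}",
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write the canonical tab-delimited layout ``snp_id chrom pos pvalue``."""
    table.df.to_csv(path, sep="\t", index=False, columns=["snp_id", "chrom", "pos", "pvalue"])
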