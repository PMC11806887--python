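"""Binary epigenomic annotation of SNPs and per-block feature maps.

A feature track is a named set of genomic intervals (BED convention, 0-based
half-open) in one of four categories: open chromatin (DHS), histone
modifications, transcription-factor binding sites, and target-gene-function
annotations. A SNP's feature vector holds a 1 for every track with an
interval covering its position; an association block becomes a fixed-height
(31 x F) binary matrix — one row per SNP slot in genomic order, zero-padded
with an explicit validity mask. Control (label-0) maps are made from
positive maps by independently permuting each feature column across the
valid rows, which preserves every per-column marginal while destroying the
SNP-feature association.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .blocks import AssociationBlock
from .gwas import SnpRecord, normalize_chrom

__all__ = [
    "CATEGORIES",
    "FeatureTrack",
    "BlockFeatureMap",
    "annotate_snp",
    "build_block_map",
    "make_control_block",
    "read_bed_track",
    "read_track_manifest",
    "write_track",
    "BLOCK_ROWS",
    "POSITIVE_CONFIDENCE",
    "CONTROL_CONFIDENCE",
]

CATEGORIES = ("DHS", "histone", "TFBS", "gene_function")

#: fixed map height: lead + 30 neighbors
BLOCK_ROWS = 31

#: default soft label confidences: a positive block contains at most one
#: truly causal SNP among its 31, so its label is trusted less than fully;
#: a shuffled control is very unlikely to recreate a causal configuration.
POSITIVE_CONFIDENCE = 0.9
CONTROL_CONFIDENCE = 0.05


@dataclass
class FeatureTrack:
    """One interval track. ``intervals`` are (chrom, start, end), 0-based half-open."""

    name: str
    category: str
    intervals: list[tuple[str, int, int]]
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval ({chrom}, {start}, {end}): need 0 <= start < end")

    def _tree(self, chrom: str) -> IntervalTree:
        if not self._trees:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for c, s, e in self.intervals:
                by_chrom.setdefault(normalize_chrom(c), []).append((s, e))
            self._trees.update(
                {c: IntervalTree.from_tuples(iv) for c, iv in by_chrom.items()}
            )
        return self._trees.get(chrom, IntervalTree())

    def covers(self, chrom: str, pos0: int) -> bool:
        """Does any interval of this track cover 0-based position ``pos0``?"""
        return bool(self._tree(normalize_chrom(chrom)).overlaps_point(pos0))


@dataclass
class BlockFeatureMap:
    """The 31 x F binary matrix fed to the CNN, plus its validity mask and label."""

    block_id: str
    trait: str
    chrom: str
    matrix: np.ndarray  # (BLOCK_ROWS, F) int8
    row_mask: np.ndarray  # (BLOCK_ROWS,) int8
    snp_ids: list[str]  # valid rows only, genomic order
    positions: np.ndarray  # (n_valid,) int64
    pvalues: np.ndarray  # (n_valid,) float64
    label: str  # "positive" | "control"
    label_confidence: float

    @property
    def n_valid(self) -> int:
        return int(self.row_mask.sum())

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def annotate_snp(snp: SnpRecord, tracks: list[FeatureTrack]) -> np.ndarray:
    """Binary feature vector of ``snp`` over ``tracks`` (order fixes columns).

    The SNP's 1-based position is converted to 0-based before the half-open
    interval test, so a track interval [99, 150) covers 1-based position 100.
    """
    pos0 = snp.pos - 1
    return np.array([1 if t.covers(snp.chrom, pos0) else 0 for t in tracks], dtype=np.int8)


def build_block_map(
    block: AssociationBlock,
    tracks: list[FeatureTrack],
    positive_confidence: float = POSITIVE_CONFIDENCE,
) -> BlockFeatureMap:
    """Assemble a block's feature map: row i annotates its i-th member in
    genomic-position order; rows beyond the member count are zero with mask 0."""
    if not tracks:
        raise ValueError("no feature tracks supplied")
    if len(block.members) > BLOCK_ROWS:
        raise ValueError(f"block {block.block_id} has more than {BLOCK_ROWS} members")
    F = len(tracks)
    matrix = np.zeros((BLOCK_ROWS, F), dtype=np.int8)
    mask = np.zeros(BLOCK_ROWS, dtype=np.int8)
    for i, m in enumerate(block.members):
        matrix[i] = annotate_snp(m, tracks)
        mask[i] = 1
    return BlockFeatureMap(
        block_id=block.block_id,
        trait=block.trait,
        chrom=block.chrom,
        matrix=matrix,
        row_mask=mask,
        snp_ids=[m.snp_id for m in block.members],
        positions=np.array([m.pos for m in block.members], dtype=np.int64),
        pvalues=np.array([m.pvalue for m in block.members], dtype=float),
        label="positive",
        label_confidence=positive_confidence,
    )


def make_control_block(
    fmap: BlockFeatureMap,
    rng: np.random.Generator,
    control_confidence: float = CONTROL_CONFIDENCE,
) -> BlockFeatureMap:
    """Shuffled-feature control: permute each column independently over the
    masked-in rows. Column sums (feature prevalences) are preserved exactly;
    row identity — which features co-occur on one SNP — is destroyed."""
    if fmap.label != "positive":
        raise ValueError("control blocks are derived from positive maps")
    k = fmap.n_valid
    matrix = fmap.matrix.copy()
    for j in range(fmap.n_features):
        matrix[:k, j] = matrix[:k, j][rng.permutation(k)]
    return replace(
        fmap,
        block_id=fmap.block_id + "::ctrl",
        matrix=matrix,
        label="control",
        label_confidence=control_confidence,
    )


# ---------------------------------------------------------------- file I/O


def read_bed_track(path, name: str, category: str) -> FeatureTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    intervals = [
        (str(c), int(s), int(e)) for c, s, e in zip(df[0], df[1], df[2])
    ]
    return FeatureTrack(name=name, category=category, intervals=intervals)


def read_track_manifest(path) -> list[FeatureTrack]:
    """A manifest file (``name<TAB>category<TAB>path``, paths relative to the
    manifest) fixes the pipeline-wide feature column order."""
    import os

    base = os.path.dirname(os.fspath(path))
    manifest = pd.read_csv(path, sep="\t")
    for col in ("name", "category", "path"):
        if col not in manifest.columns:
            raise ValueError(f"track manifest missing column {col!r}")
    tracks = []
    for row in manifest.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        tracks.append(read_bed_track(p, name=row.name, category=row.category))
    return tracks


def write_track(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(track.intervals):
            fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")
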