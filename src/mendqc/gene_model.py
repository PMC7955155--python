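"""BED12 gene models and derived genomic region categories.

A transcript annotation in BED12 carries the exon block structure and the
thick (coding) span of one transcript.  From it we derive the categorized
regions against which alignment tags are classified: CDS exons, 5'/3' UTR
exons, exons of non-coding transcripts, introns, and nested flanking
windows upstream of the transcription start site (TSS) and downstream of
the transcription end site (TES).

All coordinates are 0-based half-open (BED native) throughout the package;
conversion to/from 1-based happens only at SAM text boundaries, inside the
alignment I/O layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "RegionCategory",
    "GenomicInterval",
    "TranscriptModel",
    "RegionIndex",
    "BedParseError",
    "parse_bed12",
    "derive_regions",
    "build_region_index",
    "DEFAULT_FLANK_SIZES",
]

DEFAULT_FLANK_SIZES: tuple[int, ...] = (1000, 5000, 10000)


class RegionCategory(str, enum.Enum):
    """Region category labels, ordered here by tag-assignment precedence."""

    CDS_EXON = "CDS_EXON"
    UTR5_EXON = "UTR5_EXON"
    UTR3_EXON = "UTR3_EXON"
    NONCODING_EXON = "NONCODING_EXON"
    INTRON = "INTRON"
    TSS_UP_1K = "TSS_UP_1K"
    TES_DOWN_1K = "TES_DOWN_1K"
    TSS_UP_5K = "TSS_UP_5K"
    TES_DOWN_5K = "TES_DOWN_5K"
    TSS_UP_10K = "TSS_UP_10K"
    TES_DOWN_10K = "TES_DOWN_10K"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Tag-assignment precedence, highest first.  Exonic categories outrank
#: introns, which outrank the flanks; among flanks the narrower window wins.
CATEGORY_PRECEDENCE: tuple[RegionCategory, ...] = (
    RegionCategory.CDS_EXON,
    RegionCategory.UTR5_EXON,
    RegionCategory.UTR3_EXON,
    RegionCategory.NONCODING_EXON,
    RegionCategory.INTRON,
    RegionCategory.TSS_UP_1K,
    RegionCategory.TES_DOWN_1K,
    RegionCategory.TSS_UP_5K,
    RegionCategory.TES_DOWN_5K,
    RegionCategory.TSS_UP_10K,
    RegionCategory.TES_DOWN_10K,
)

#: Categories whose tags count toward the MEND estimate by default.
EXONIC_CATEGORIES: frozenset[RegionCategory] = frozenset(
    {
        RegionCategory.CDS_EXON,
        RegionCategory.UTR5_EXON,
        RegionCategory.UTR3_EXON,
        RegionCategory.NONCODING_EXON,
    }
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval carrying a region category."""

    chrom: str
    start: int
    end: int
    category: RegionCategory

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """One BED12 record: exon blocks plus the thick (CDS) span on a strand."""

    chrom: str
    tx_start: int
    tx_end: int
    name: str
    strand: str
    thick_start: int
    thick_end: int
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.tx_start <= self.tx_end:
            raise ValueError("txStart must be <= txEnd")
        if not self.thick_start <= self.thick_end:
            raise ValueError("thickStart must be <= thickEnd")
        if self.thick_start != self.thick_end and not (
            self.tx_start <= self.thick_start and self.thick_end <= self.tx_end
        ):
            raise ValueError("thick region outside transcript span")
        prev_end = None
        for start, end in self.blocks:
            if not (self.tx_start <= start < end <= self.tx_end):
                raise ValueError(f"block [{start},{end}) outside transcript span")
            if prev_end is not None and start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = end
        if self.blocks:
            if self.blocks[0][0] != self.tx_start or self.blocks[-1][1] != self.tx_end:
                raise ValueError("blocks must span txStart..txEnd")

    @property
    def is_coding(self) -> bool:
        return self.thick_start < self.thick_end

    def block_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def dedup_key(self) -> tuple:
        return (self.chrom, self.tx_start, self.tx_end, self.strand, self.blocks)


class BedParseError(ValueError):
    """Raised for a malformed BED12 line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"BED12 parse error at line {line_number}: {message}")


def parse_bed12(path: str) -> list[TranscriptModel]:
    """Parse a 12-column BED file into transcript models.

    blockSizes/blockStarts may carry a trailing comma (UCSC convention).
    Lines violating the BED12 invariants raise :class:`BedParseError`
    naming the offending line.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise BedParseError(lineno, f"expected 12 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                tx_start, tx_end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
                starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
            except ValueError as exc:
                raise BedParseError(lineno, f"bad numeric field: {exc}") from None
            if len(sizes) != block_count or len(starts) != block_count:
                raise BedParseError(
                    lineno,
                    f"blockCount {block_count} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts",
                )
            blocks = tuple(
                (tx_start + off, tx_start + off + size)
                for off, size in zip(starts, sizes)
            )
            try:
                models.append(
                    TranscriptModel(
                        chrom=chrom,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        name=name,
                        strand=strand,
                        thick_start=thick_start,
                        thick_end=thick_end,
                        blocks=blocks,
                    )
                )
            except ValueError as exc:
                raise BedParseError(lineno, str(exc)) from None
    return models


def _flank_intervals(
    tx: TranscriptModel, flank_sizes: Sequence[int]
) -> list[GenomicInterval]:
    """Nested windows upstream of the TSS and downstream of the TES.

    Windows share the transcript-proximal edge (nested, not tiled) and are
    clipped at coordinate 0.  On the minus strand the TSS sits at tx_end and
    upstream extends to higher coordinates.
    """
    up_cats = (RegionCategory.TSS_UP_1K, RegionCategory.TSS_UP_5K, RegionCategory.TSS_UP_10K)
    down_cats = (RegionCategory.TES_DOWN_1K, RegionCategory.TES_DOWN_5K, RegionCategory.TES_DOWN_10K)
    out: list[GenomicInterval] = []
    for size, up_cat, down_cat in zip(flank_sizes, up_cats, down_cats):
        if tx.strand == "+":
            up = (max(0, tx.tx_start - size), tx.tx_start)
            down = (tx.tx_end, tx.tx_end + size)
        else:
            up = (tx.tx_end, tx.tx_end + size)
            down = (max(0, tx.tx_start - size), tx.tx_start)
        for (s, e), cat in ((up, up_cat), (down, down_cat)):
            if s < e:
                out.append(GenomicInterval(tx.chrom, s, e, cat))
    return out


def derive_regions(
    tx: TranscriptModel,
    flank_sizes: Sequence[int] = DEFAULT_FLANK_SIZES,
) -> list[GenomicInterval]:
    """Split a transcript into categorized genomic intervals.

    Coding transcripts yield CDS exon pieces (block ∩ thick span) and UTR
    exon pieces, with 5'/3' assignment following transcription order on the
    strand.  Non-coding transcripts (thickStart == thickEnd) yield their
    whole blocks as NONCODING_EXON.  Gaps between consecutive blocks are
    introns; flanking windows are produced by :func:`_flank_intervals`.
    """
    out: list[GenomicInterval] = []
    if tx.is_coding:
        # upstream-of-CDS exon pieces are 5'UTR on +, 3'UTR on -
        left_cat = RegionCategory.UTR5_EXON if tx.strand == "+" else RegionCategory.UTR3_EXON
        right_cat = RegionCategory.UTR3_EXON if tx.strand == "+" else RegionCategory.UTR5_EXON
        for bs, be in tx.blocks:
            left = (bs, min(be, tx.thick_start))
            cds = (max(bs, tx.thick_start), min(be, tx.thick_end))
            right = (max(bs, tx.thick_end), be)
            if left[0] < left[1]:
                out.append(GenomicInterval(tx.chrom, left[0], left[1], left_cat))
            if cds[0] < cds[1]:
                out.append(GenomicInterval(tx.chrom, cds[0], cds[1], RegionCategory.CDS_EXON))
            if right[0] < right[1]:
                out.append(GenomicInterval(tx.chrom, right[0], right[1], right_cat))
    else:
        for bs, be in tx.blocks:
            out.append(GenomicInterval(tx.chrom, bs, be, RegionCategory.NONCODING_EXON))
    for (_, prev_end), (next_start, _) in zip(tx.blocks, tx.blocks[1:]):
        if prev_end < next_start:
            out.append(GenomicInterval(tx.chrom, prev_end, next_start, RegionCategory.INTRON))
    out.extend(_flank_intervals(tx, flank_sizes))
    return out


@dataclass
class RegionIndex:
    """Per-chromosome interval index from query intervals to categories.

    Overlap queries return the set of every overlapped category; precedence
    between categories is applied later, at tag assignment.
    """

    flank_sizes: tuple[int, ...] = DEFAULT_FLANK_SIZES
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.category)

    def lookup(self, chrom: str, start: int, end: int) -> set[RegionCategory]:
        """Categories of all indexed intervals overlapping [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(start, end)}

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)


def build_region_index(
    models: Iterable[TranscriptModel],
    flank_sizes: Sequence[int] = DEFAULT_FLANK_SIZES,
) -> RegionIndex:
    """Index the derived regions of every (de-duplicated) transcript.

    Transcripts identical in (chrom, span, strand, blocks) are collapsed
    first so that redundant annotation rows cannot change assignment
    outcomes.  An empty model list is a configuration error.
    """
    models = list(models)
    if not models:
        raise ValueError("cannot build a region index from an empty gene model")
    seen: set[tuple] = set()
    idx = RegionIndex(flank_sizes=tuple(flank_sizes))
    for tx in models:
        key = tx.dedup_key()
        if key in seen:
            continue
        seen.add(key)
        for iv in derive_regions(tx, flank_sizes):
            idx.add(iv)
    return idx
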