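"""Minimal alignment data model and SAM/BAM I/O.

Wraps pysam for reading and writing while exposing exactly the fields the
MEND computation needs: flag booleans, the CIGAR, splice-split aligned
blocks ("tags"), and the unclipped 5' position used in duplicate
signatures.  Coordinates are 0-based half-open internally; pysam handles
the SAM text conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "FlagSet",
    "AlignmentRecord",
    "read_alignments",
    "write_alignments",
    "unclipped_five_prime",
    "aligned_blocks",
    "make_header",
]

# SAM flag bits
FPAIRED = 0x1
FPROPER = 0x2
FUNMAP = 0x4
FMUNMAP = 0x8
FREVERSE = 0x10
FMREVERSE = 0x20
FREAD1 = 0x40
FREAD2 = 0x80
FSECONDARY = 0x100
FQCFAIL = 0x200
FDUP = 0x400
FSUPPLEMENTARY = 0x800

#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")
#: CIGAR operations that consume query bases.
QUERY_CONSUMING = frozenset("MIS=X")
_CIGAR_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class FlagSet:
    """Decoded SAM flag bits."""

    paired: bool = False
    proper_pair: bool = False
    unmapped: bool = False
    mate_unmapped: bool = False
    reverse: bool = False
    mate_reverse: bool = False
    first_in_pair: bool = False
    second_in_pair: bool = False
    secondary: bool = False
    qc_fail: bool = False
    duplicate: bool = False
    supplementary: bool = False

    def __post_init__(self) -> None:
        if self.first_in_pair and self.second_in_pair:
            raise ValueError("a read cannot be both first and second in pair")

    @classmethod
    def from_int(cls, flag: int) -> "FlagSet":
        return cls(
            paired=bool(flag & FPAIRED),
            proper_pair=bool(flag & FPROPER),
            unmapped=bool(flag & FUNMAP),
            mate_unmapped=bool(flag & FMUNMAP),
            reverse=bool(flag & FREVERSE),
            mate_reverse=bool(flag & FMREVERSE),
            first_in_pair=bool(flag & FREAD1),
            second_in_pair=bool(flag & FREAD2),
            secondary=bool(flag & FSECONDARY),
            qc_fail=bool(flag & FQCFAIL),
            duplicate=bool(flag & FDUP),
            supplementary=bool(flag & FSUPPLEMENTARY),
        )

    def to_int(self) -> int:
        flag = 0
        for bit, val in (
            (FPAIRED, self.paired),
            (FPROPER, self.proper_pair),
            (FUNMAP, self.unmapped),
            (FMUNMAP, self.mate_unmapped),
            (FREVERSE, self.reverse),
            (FMREVERSE, self.mate_reverse),
            (FREAD1, self.first_in_pair),
            (FREAD2, self.second_in_pair),
            (FSECONDARY, self.secondary),
            (FQCFAIL, self.qc_fail),
            (FDUP, self.duplicate),
            (FSUPPLEMENTARY, self.supplementary),
        ):
            if val:
                flag |= bit
        return flag


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment.

    ``cigar`` is a tuple of (op, length) with op a CIGAR letter; it is None
    for unmapped records, as are ``ref`` and ``pos``.
    """

    qname: str
    flags: FlagSet
    ref: str | None = None
    pos: int | None = None
    mapq: int = 0
    cigar: tuple[tuple[str, int], ...] | None = None
    mate_ref: str | None = None
    mate_pos: int | None = None
    tlen: int = 0

    def __post_init__(self) -> None:
        if self.flags.unmapped:
            if self.cigar is not None:
                raise ValueError("unmapped record must not carry a CIGAR")
        else:
            if self.ref is None or self.pos is None or self.pos < 0:
                raise ValueError("mapped record needs ref and non-negative pos")
            if self.cigar is not None:
                for op, length in self.cigar:
                    if op not in _CIGAR_OPS or length < 1:
                        raise ValueError(f"bad CIGAR element {op}{length}")

    @property
    def is_mapped(self) -> bool:
        return not self.flags.unmapped

    @property
    def is_primary(self) -> bool:
        return not (self.flags.secondary or self.flags.supplementary)

    def with_duplicate(self, duplicate: bool) -> "AlignmentRecord":
        if self.flags.duplicate == duplicate:
            return self
        return replace(self, flags=replace(self.flags, duplicate=duplicate))


def make_header(references: Sequence[tuple[str, int]], sort_order: str = "coordinate") -> dict:
    """Build a pysam-style header dict for the given (name, length) refs."""
    return {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = None
    if not seg.is_unmapped and seg.cigartuples:
        cigar = tuple((_CIGAR_OPS[op], length) for op, length in seg.cigartuples)
    return AlignmentRecord(
        qname=seg.query_name,
        flags=FlagSet.from_int(seg.flag),
        ref=None if seg.is_unmapped else seg.reference_name,
        pos=None if seg.is_unmapped else seg.reference_start,
        mapq=seg.mapping_quality,
        cigar=cigar,
        mate_ref=None if seg.next_reference_id < 0 else seg.next_reference_name,
        mate_pos=None if seg.next_reference_id < 0 else seg.next_reference_start,
        tlen=seg.template_length,
    )


def _to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.qname
    seg.flag = rec.flags.to_int()
    seg.reference_id = -1 if rec.ref is None else header.get_tid(rec.ref)
    seg.reference_start = -1 if rec.pos is None else rec.pos
    seg.mapping_quality = rec.mapq
    if rec.cigar is not None:
        seg.cigartuples = [(_CIGAR_OPS.index(op), length) for op, length in rec.cigar]
    seg.next_reference_id = -1 if rec.mate_ref is None else header.get_tid(rec.mate_ref)
    seg.next_reference_start = -1 if rec.mate_pos is None else rec.mate_pos
    seg.template_length = rec.tlen
    return seg


def read_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Yield records from a SAM or BAM file in file order.

    The file must have a header (references are needed to resolve names).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if not fh.header.get("SQ") and not fh.header.get("HD"):
            raise IOError(f"{path}: missing SAM/BAM header")
        for seg in fh.fetch(until_eof=True):
            yield _from_pysam(seg)


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str,
    header: dict,
) -> None:
    """Write records to SAM (.sam) or BAM (anything else) under ``header``.

    If the header declares coordinate sorting, the mapped records must
    arrive sorted by (reference order, position); placed-unmapped and
    unplaced records are accepted anywhere after their reference block.
    """
    path = str(path)
    mode = "w" if path.endswith(".sam") else "wb"
    sort_order = header.get("HD", {}).get("SO", "unknown")
    with pysam.AlignmentFile(path, mode, header=header) as out:
        prev_key: tuple[int, int] | None = None
        for rec in records:
            seg = _to_pysam(rec, out.header)
            if sort_order == "coordinate" and seg.reference_id >= 0:
                key = (seg.reference_id, seg.reference_start)
                if prev_key is not None and key < prev_key:
                    raise ValueError(
                        "records not coordinate-sorted but header declares SO:coordinate"
                    )
                prev_key = key
            out.write(seg)


def unclipped_five_prime(rec: AlignmentRecord) -> int:
    """Position of the read's 5' end as if clipping had not occurred.

    Forward strand: leftmost aligned position minus leading S/H clips.
    Reverse strand: rightmost aligned position (inclusive) plus trailing
    S/H clips.  Hard and soft clips are treated alike so that a clipped
    duplicate produces the same signature as its unclipped twin.
    """
    if not rec.is_mapped or not rec.cigar:
        raise ValueError("unclipped_five_prime requires a mapped record with a CIGAR")
    cigar = rec.cigar
    if not rec.flags.reverse:
        lead = 0
        for op, length in cigar:
            if op in "SH":
                lead += length
            else:
                break
        return rec.pos - lead
    ref_span = sum(length for op, length in cigar if op in REF_CONSUMING)
    trail = 0
    for op, length in reversed(cigar):
        if op in "SH":
            trail += length
        else:
            break
    return rec.pos + ref_span - 1 + trail


def aligned_blocks(rec: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference intervals ("tags") covered by the alignment, split at N.

    M/=/X/D extend the current block; N (splice skip) closes it and opens a
    new one; I/S/H/P consume no reference.  A spliced RNA-seq read thus
    yields one tag per exon-contact segment.
    """
    if not rec.is_mapped or not rec.cigar:
        raise ValueError("aligned_blocks requires a mapped record with a CIGAR")
    blocks: list[tuple[int, int]] = []
    cursor = rec.pos
    block_start: int | None = None
    for op, length in rec.cigar:
        if op in "M=XD":
            if block_start is None:
                block_start = cursor
            cursor += length
        elif op == "N":
            if block_start is not None and cursor > block_start:
                blocks.append((block_start, cursor))
            cursor += length
            block_start = None
        # I, S, H, P: no reference consumed, block continues
    if block_start is not None and cursor > block_start:
        blocks.append((block_start, cursor))
    return blocks
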