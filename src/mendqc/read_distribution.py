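"""Read-type classification, tag-to-region assignment, and MEND estimation.

Every alignment record falls into exactly one read-type bucket, tested in
precedence order: UNMAPPED, SECONDARY, SUPPLEMENTARY, QC_FAIL, DUPLICATE,
USABLE.  Only usable records (mapped, primary, non-supplementary, not
QC-fail, not duplicate) contribute tags: the splice-split aligned blocks
of the read.  Each tag is assigned to the highest-precedence region
category it overlaps, and the MEND read count is estimated as

    mend_reads = exonic_tags * (usable_reads / total_tags)

i.e. the exonic tag count converted back to reads through the dataset's
reads-per-tag ratio.  Depth figures are additionally reported in pairs
(read count halved, truncating), the convention used throughout.

Exonic means CDS exon, 5'UTR exon or 3'UTR exon tags, plus tags in exons
of non-coding transcripts unless ``coding_only`` is requested: non-coding
genes contribute to expression quantification, so their reads count as
exonic by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

from .alignment_model import AlignmentRecord, aligned_blocks
from .gene_model import (
    CATEGORY_PRECEDENCE,
    EXONIC_CATEGORIES,
    RegionCategory,
    RegionIndex,
)

__all__ = [
    "ReadType",
    "ReadTypeTally",
    "MendResult",
    "classify_record",
    "assign_tag",
    "tally_dataset",
    "estimate_mend",
    "render_report_tsv",
    "render_report_json",
]

UNASSIGNED = "UNASSIGNED"


class ReadType:
    UNMAPPED = "UNMAPPED"
    SECONDARY = "SECONDARY"
    SUPPLEMENTARY = "SUPPLEMENTARY"
    QC_FAIL = "QC_FAIL"
    DUPLICATE = "DUPLICATE"
    USABLE = "USABLE"


def classify_record(rec: AlignmentRecord) -> str:
    """Read-type label of a record, by fixed precedence."""
    if rec.flags.unmapped:
        return ReadType.UNMAPPED
    if rec.flags.secondary:
        return ReadType.SECONDARY
    if rec.flags.supplementary:
        return ReadType.SUPPLEMENTARY
    if rec.flags.qc_fail:
        return ReadType.QC_FAIL
    if rec.flags.duplicate:
        return ReadType.DUPLICATE
    return ReadType.USABLE


def assign_tag(tag: tuple[int, int], chrom: str, idx: RegionIndex) -> str:
    """Highest-precedence region category overlapped by a tag.

    Precedence: CDS exon > 5'UTR exon > 3'UTR exon > non-coding exon >
    intron > TSS 1k > TES 1k > TSS 5k > TES 5k > TSS 10k > TES 10k.
    A tag overlapping no indexed region is UNASSIGNED.
    """
    start, end = tag
    if start >= end:
        raise ValueError(f"empty tag interval [{start},{end})")
    cats = idx.lookup(chrom, start, end)
    if not cats:
        return UNASSIGNED
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat.value
    return UNASSIGNED  # pragma: no cover - precedence list is exhaustive


@dataclass
class ReadTypeTally:
    """Dataset-level read-type and tag counters.

    ``mapped`` counts mapped primary records; secondary/supplementary sit
    in diagnostic buckets outside the mapped/unmapped split.
    """

    total_records: int = 0
    unmapped: int = 0
    mapped: int = 0
    qc_fail: int = 0
    secondary: int = 0
    supplementary: int = 0
    duplicates: int = 0
    usable: int = 0
    total_tags: int = 0
    assigned_tags: dict[str, int] = field(default_factory=dict)
    unassigned_tags: int = 0

    def check_conservation(self) -> None:
        """Assert the counting hierarchy sums; raises on violation."""
        if self.unmapped + self.mapped != self.total_records - (
            self.secondary + self.supplementary
        ):
            raise AssertionError("unmapped + mapped != primary records")
        if self.qc_fail + self.duplicates + self.usable != self.mapped:
            raise AssertionError("qc_fail + duplicates + usable != mapped")
        if sum(self.assigned_tags.values()) + self.unassigned_tags != self.total_tags:
            raise AssertionError("assigned + unassigned tags != total tags")
        if any(
            v < 0
            for v in (
                self.total_records,
                self.unmapped,
                self.mapped,
                self.qc_fail,
                self.secondary,
                self.supplementary,
                self.duplicates,
                self.usable,
                self.total_tags,
                self.unassigned_tags,
                *self.assigned_tags.values(),
            )
        ):
            raise AssertionError("negative counter")

    def exonic_tags(self, coding_only: bool = False) -> int:
        cats = [RegionCategory.CDS_EXON, RegionCategory.UTR5_EXON, RegionCategory.UTR3_EXON]
        if not coding_only:
            cats.append(RegionCategory.NONCODING_EXON)
        return sum(self.assigned_tags.get(c.value, 0) for c in cats)


@dataclass(frozen=True)
class MendResult:
    """MEND estimate and the hierarchical read-type fractions."""

    mend_tags: int
    reads_per_tag: float
    mend_reads: int
    mend_pairs: int
    unmapped_of_total: float
    duplicate_of_mapped: float
    nonexonic_of_mapped_nondup: float
    mend_of_total: float


def tally_dataset(
    records: Iterable[AlignmentRecord], idx: RegionIndex
) -> ReadTypeTally:
    """Classify a duplicate-marked record stream and count tags per category.

    Empty input yields an all-zero tally.  Conservation of the counting
    hierarchy is asserted before returning.
    """
    t = ReadTypeTally()
    assigned: dict[str, int] = {}
    for rec in records:
        t.total_records += 1
        rt = classify_record(rec)
        if rt == ReadType.UNMAPPED:
            t.unmapped += 1
            continue
        if rt == ReadType.SECONDARY:
            t.secondary += 1
            continue
        if rt == ReadType.SUPPLEMENTARY:
            t.supplementary += 1
            continue
        t.mapped += 1
        if rt == ReadType.QC_FAIL:
            t.qc_fail += 1
            continue
        if rt == ReadType.DUPLICATE:
            t.duplicates += 1
            continue
        t.usable += 1
        for block in aligned_blocks(rec):
            t.total_tags += 1
            cat = assign_tag(block, rec.ref, idx)
            if cat == UNASSIGNED:
                t.unassigned_tags += 1
            else:
                assigned[cat] = assigned.get(cat, 0) + 1
    t.assigned_tags = assigned
    t.check_conservation()
    return t


def _safe_frac(num: float, den: float) -> float:
    return num / den if den else 0.0


def estimate_mend(tally: ReadTypeTally, coding_only: bool = False) -> MendResult:
    """Estimate MEND reads from a tally.

    ``mend_reads`` is exonic tags times reads-per-tag, rounded half up;
    ``mend_pairs`` halves it, truncating.  All 0/0 fractions are defined
    as 0 so that empty or fully-excluded datasets report zeros.
    """
    mend_tags = tally.exonic_tags(coding_only=coding_only)
    reads_per_tag = _safe_frac(tally.usable, tally.total_tags)
    mend_reads = int(math.floor(mend_tags * reads_per_tag + 0.5))
    total_primary = tally.unmapped + tally.mapped
    return MendResult(
        mend_tags=mend_tags,
        reads_per_tag=reads_per_tag,
        mend_reads=mend_reads,
        mend_pairs=mend_reads // 2,
        unmapped_of_total=_safe_frac(tally.unmapped, total_primary),
        duplicate_of_mapped=_safe_frac(tally.duplicates, tally.mapped),
        nonexonic_of_mapped_nondup=_safe_frac(tally.usable - mend_reads, tally.usable),
        mend_of_total=_safe_frac(mend_reads, total_primary),
    )


def _report_rows(tally: ReadTypeTally, result: MendResult) -> list[tuple]:
    total_primary = tally.unmapped + tally.mapped
    rows = [
        ("total_primary_records", tally.total_records - tally.secondary - tally.supplementary, total_primary, 1.0, "reads"),
        ("unmapped", tally.unmapped, total_primary, result.unmapped_of_total, "reads"),
        ("mapped", tally.mapped, total_primary, 1.0 - result.unmapped_of_total, "reads"),
        ("qc_fail", tally.qc_fail, tally.mapped, _safe_frac(tally.qc_fail, tally.mapped), "reads"),
        ("duplicates", tally.duplicates, tally.mapped, result.duplicate_of_mapped, "reads"),
        ("usable", tally.usable, tally.mapped, _safe_frac(tally.usable, tally.mapped), "reads"),
        ("secondary", tally.secondary, tally.total_records, _safe_frac(tally.secondary, tally.total_records), "reads"),
        ("supplementary", tally.supplementary, tally.total_records, _safe_frac(tally.supplementary, tally.total_records), "reads"),
        ("mend_reads", result.mend_reads, total_primary, result.mend_of_total, "reads"),
        ("mend_pairs", result.mend_pairs, total_primary // 2, result.mend_of_total, "pairs"),
    ]
    return rows


def render_report_tsv(tally: ReadTypeTally, result: MendResult) -> str:
    """TSV report: hierarchy rows, per-category tag block, MEND summary."""
    lines = ["metric\tcount\tdenominator\tfraction\tunit"]
    for name, count, den, frac, unit in _report_rows(tally, result):
        lines.append(f"{name}\t{count}\t{den}\t{frac:.6f}\t{unit}")
    lines.append("")
    lines.append("category\ttag_count")
    for cat in CATEGORY_PRECEDENCE:
        lines.append(f"{cat.value}\t{tally.assigned_tags.get(cat.value, 0)}")
    lines.append(f"UNASSIGNED\t{tally.unassigned_tags}")
    lines.append(f"TOTAL_TAGS\t{tally.total_tags}")
    lines.append("")
    lines.append(
        "MEND\tmend_tags=%d\treads_per_tag=%.6f\tmend_reads=%d\tmend_pairs=%d"
        % (result.mend_tags, result.reads_per_tag, result.mend_reads, result.mend_pairs)
    )
    return "\n".join(lines) + "\n"


def render_report_json(
    tally: ReadTypeTally, result: MendResult, extra: dict | None = None
) -> str:
    payload = {
        "tally": {
            "total_records": tally.total_records,
            "unmapped": tally.unmapped,
            "mapped": tally.mapped,
            "qc_fail": tally.qc_fail,
            "secondary": tally.secondary,
            "supplementary": tally.supplementary,
            "duplicates": tally.duplicates,
            "usable": tally.usable,
            "total_tags": tally.total_tags,
            "assigned_tags": dict(sorted(tally.assigned_tags.items())),
            "unassigned_tags": tally.unassigned_tags,
        },
        "mend": {
            "mend_tags": result.mend_tags,
            "reads_per_tag": result.reads_per_tag,
            "mend_reads": result.mend_reads,
            "mend_pairs": result.mend_pairs,
            "fractions": {
                "unmapped_of_total": result.unmapped_of_total,
                "duplicate_of_mapped": result.duplicate_of_mapped,
                "nonexonic_of_mapped_nondup": result.nonexonic_of_mapped_nondup,
                "mend_of_total": result.mend_of_total,
            },
        },
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2) + "\n"
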