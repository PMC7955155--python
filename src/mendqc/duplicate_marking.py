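"""Signature-based duplicate marking of paired-end alignments.

A fragment's signature is the (reference, unclipped 5' position, strand)
of each of its mapped ends, in canonical order, so that two record pairs
derived from the same physical fragment collide regardless of clipping or
of which mate appears first in the file.  Within a signature group the
first-encountered fragment (file order) stays unmarked and every later one
has the duplicate flag set on both mates.  Fragments with a single mapped
end (orphans) are compared only against other orphans; pairs where both
mates are unmapped are never marked.

Secondary and supplementary alignments never enter signatures and are
never flagged here.  There is no optical-duplicate distinction and no
quality-based survivor selection: marking is order-deterministic for a
fixed file.  Signatures for the whole dataset are held in memory; the tool
targets desk-scale datasets and synthetic fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment_model import AlignmentRecord, unclipped_five_prime

__all__ = ["FragmentSignature", "fragment_signature", "mark_duplicates"]

logger = logging.getLogger(__name__)

End = tuple[str, int, str]  # (reference, unclipped 5' coordinate, strand)


@dataclass(frozen=True)
class FragmentSignature:
    """Canonical identity of a sequenced fragment."""

    kind: str  # "PAIR" or "ORPHAN"
    end1: End
    end2: End | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("PAIR", "ORPHAN"):
            raise ValueError(f"kind must be PAIR or ORPHAN, got {self.kind!r}")
        if self.kind == "PAIR":
            if self.end2 is None:
                raise ValueError("PAIR signature requires two ends")
            if self.end2 < self.end1:
                raise ValueError("PAIR signature ends must be in canonical order")
        elif self.end2 is not None:
            raise ValueError("ORPHAN signature carries a single end")


def _end_of(rec: AlignmentRecord) -> End:
    strand = "-" if rec.flags.reverse else "+"
    return (rec.ref, unclipped_five_prime(rec), strand)


def fragment_signature(
    rec: AlignmentRecord, mate_end: End | None = None
) -> FragmentSignature:
    """Signature of the fragment ``rec`` belongs to.

    ``mate_end`` is the mate's (ref, unclipped 5', strand) if the mate is
    mapped, or None for an orphan.  Ends are sorted so both mates produce
    the same signature.
    """
    if not rec.is_mapped:
        raise ValueError("cannot compute a signature for an unmapped record")
    this_end = _end_of(rec)
    if mate_end is None:
        return FragmentSignature(kind="ORPHAN", end1=this_end)
    end1, end2 = sorted((this_end, mate_end))
    return FragmentSignature(kind="PAIR", end1=end1, end2=end2)


def mark_duplicates(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], int]:
    """Mark duplicate fragments; return (records, duplicate fragment count).

    Existing duplicate flags are ignored and recomputed, which makes the
    operation idempotent.  Records are grouped by query name; fragments are
    processed in order of first appearance in the input.  A mapped primary
    record whose mate record is missing from the stream triggers a warning
    and is treated as an orphan.
    """
    records = list(records)

    # group primary records by qname, remembering first-appearance order
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, rec in enumerate(records):
        if not rec.is_primary:
            continue
        if rec.qname not in groups:
            groups[rec.qname] = []
            order.append(rec.qname)
        groups[rec.qname].append(i)

    seen: set[FragmentSignature] = set()
    dup_fragments = 0
    out = list(records)
    for qname in order:
        idxs = groups[qname]
        mapped = [i for i in idxs if records[i].is_mapped]
        if not mapped:
            # both mates unmapped (or unpaired unmapped): never marked
            for i in idxs:
                out[i] = records[i].with_duplicate(False)
            continue
        if len(mapped) == 1:
            rec = records[mapped[0]]
            if rec.flags.paired and not rec.flags.mate_unmapped:
                logger.warning(
                    "mate of %s not found in stream; treating as orphan", qname
                )
            sig = fragment_signature(rec, None)
        else:
            if len(mapped) > 2:
                raise ValueError(
                    f"{qname}: more than two mapped primary records in one template"
                )
            a, b = (records[i] for i in mapped)
            sig = fragment_signature(a, _end_of(b))
        is_dup = sig in seen
        if is_dup:
            dup_fragments += 1
        else:
            seen.add(sig)
        for i in idxs:
            out[i] = records[i].with_duplicate(is_dup)
    return out, dup_fragments


def brute_force_duplicate_flags(records: Sequence[AlignmentRecord]) -> list[bool]:
    """All-pairs reference oracle: duplicate flag per input record.

    Compares every fragment's signature against every earlier fragment's,
    independently of the map-based path in :func:`mark_duplicates`.  Used
    only in testing; quadratic in the number of fragments.
    """
    records = list(records)
    frag_order: list[str] = []
    by_qname: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        if not rec.is_primary:
            continue
        if rec.qname not in by_qname:
            by_qname[rec.qname] = []
            frag_order.append(rec.qname)
        by_qname[rec.qname].append(i)

    def sig_of(qname: str) -> FragmentSignature | None:
        mapped = [records[i] for i in by_qname[qname] if records[i].is_mapped]
        if not mapped:
            return None
        if len(mapped) == 1:
            return fragment_signature(mapped[0], None)
        return fragment_signature(mapped[0], _end_of(mapped[1]))

    sigs = {q: sig_of(q) for q in frag_order}
    dup_by_qname: dict[str, bool] = {}
    for j, q in enumerate(frag_order):
        s = sigs[q]
        dup_by_qname[q] = s is not None and any(
            sigs[frag_order[k]] == s for k in range(j)
        )
    return [
        dup_by_qname.get(rec.qname, False) if rec.is_primary else rec.flags.duplicate
        for rec in records
    ]
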