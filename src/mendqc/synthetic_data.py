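"""Ground-truthed synthetic inputs for the MEND pipeline and the survey.

Two levels of simulation:

* :func:`simulate_gene_model` + :func:`simulate_alignments` build a toy
  multi-transcript gene model and a flag-correct, coordinate-sorted
  paired-end alignment file with exactly planted read-type composition
  (unmapped, duplicate, non-exonic fractions, spliced CIGARs, soft-clip
  variants, half-mapped pairs).  Counts are planted exactly — floors of
  the target fractions, not Bernoulli draws — so the accompanying
  :class:`TruthTable` is an exact oracle for the counting pipeline, not a
  statistical one.

* :func:`simulate_survey_table` builds a cohort survey table with
  Beta-distributed read-type fractions, cohort-level location shifts,
  log-normal total depth, and a Gaussian-copula rank dependence between
  depth and duplicate fraction at a configurable Spearman rho.

The default composition emulates the medians observed across large bulk
RNA-seq tumor surveys: ~3% unmapped reads, ~27% duplicates of mapped
reads, ~25% non-exonic among mapped non-duplicates, 101-base reads, and
a depth-duplicate Spearman correlation of 0.52.

The generators produce no sequence-content realism: bases and qualities
are placeholders, and there is no error model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .alignment_model import AlignmentRecord, FlagSet, make_header, write_alignments
from .gene_model import (
    EXONIC_CATEGORIES,
    GenomicInterval,
    RegionCategory,
    TranscriptModel,
    derive_regions,
)
from .read_distribution import MendResult, ReadTypeTally, estimate_mend

__all__ = [
    "SimulationSpec",
    "TruthTable",
    "simulate_gene_model",
    "simulate_alignments",
    "simulate_survey_table",
    "bed12_line",
]

def _references(models: Sequence[TranscriptModel]) -> list[tuple[str, int]]:
    """Reference sequences implied by a model: each chromosome long enough
    to hold its annotations, flanks and a trailing desert."""
    chroms = sorted({tx.chrom for tx in models})
    return [
        (c, max(tx.tx_end for tx in models if tx.chrom == c) + 120_000)
        for c in chroms
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """Targets for one synthetic alignment dataset.

    Fractions follow the counting hierarchy: ``unmapped_frac`` of total
    pairs, ``duplicate_frac`` of mapped fragments, ``nonexonic_frac`` of
    mapped non-duplicate fragments.  ``orphan_frac`` of total pairs are
    half-mapped (one mate unmapped) to exercise orphan duplicate
    signatures; ``qc_fail_frac`` of unique mapped pairs carry the QC-fail
    flag.  Planting uses exact floors of these targets.
    """

    n_pairs: int = 1000
    unmapped_frac: float = 0.03
    duplicate_frac: float = 0.27
    nonexonic_frac: float = 0.25
    splice_prob: float = 0.2
    clip_prob: float = 0.15
    orphan_frac: float = 0.02
    qc_fail_frac: float = 0.0
    read_length: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unmapped_frac", "duplicate_frac", "nonexonic_frac",
                     "splice_prob", "clip_prob", "orphan_frac", "qc_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.read_length < 40:
            raise ValueError("read_length must be >= 40")


@dataclass
class TruthTable:
    """Planted per-read-type and per-category counts for one dataset."""

    n_pairs: int
    unmapped_reads: int = 0
    mapped_reads: int = 0
    qc_fail_reads: int = 0
    duplicate_reads: int = 0
    usable_reads: int = 0
    duplicate_fragments: int = 0
    assigned_tags: dict[str, int] = field(default_factory=dict)
    unassigned_tags: int = 0
    total_tags: int = 0

    def add_tag(self, category: str | None) -> None:
        self.total_tags += 1
        if category is None:
            self.unassigned_tags += 1
        else:
            self.assigned_tags[category] = self.assigned_tags.get(category, 0) + 1

    def to_tally(self) -> ReadTypeTally:
        t = ReadTypeTally(
            total_records=2 * self.n_pairs,
            unmapped=self.unmapped_reads,
            mapped=self.mapped_reads,
            qc_fail=self.qc_fail_reads,
            duplicates=self.duplicate_reads,
            usable=self.usable_reads,
            total_tags=self.total_tags,
            assigned_tags=dict(self.assigned_tags),
            unassigned_tags=self.unassigned_tags,
        )
        t.check_conservation()
        return t

    def expected_mend(self, coding_only: bool = False) -> MendResult:
        return estimate_mend(self.to_tally(), coding_only=coding_only)


# ---------------------------------------------------------------------------
# gene model


def bed12_line(tx: TranscriptModel) -> str:
    sizes = ",".join(str(e - s) for s, e in tx.blocks) + ","
    starts = ",".join(str(s - tx.tx_start) for s, e in tx.blocks) + ","
    return "\t".join(
        str(x)
        for x in (
            tx.chrom, tx.tx_start, tx.tx_end, tx.name, 0, tx.strand,
            tx.thick_start, tx.thick_end, 0, len(tx.blocks), sizes, starts,
        )
    )


def simulate_gene_model(
    seed: int, bed_path: str | None = None
) -> tuple[str, list[TranscriptModel]]:
    """A toy gene model: 4 transcripts over 2 chromosomes.

    Includes a plus-strand multi-exon coding transcript, a single-exon
    fully coding transcript, a non-coding two-exon transcript and a
    minus-strand multi-exon coding transcript.  Transcripts are separated
    by >= 60 kb so 10 kb flanks never reach a neighbour, and every
    chromosome keeps an unannotated desert of >= 20 kb.  The seed jitters
    exon lengths; the same seed reproduces the model byte for byte.
    """
    rng = np.random.default_rng(seed)

    def j(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    models: list[TranscriptModel] = []

    # chrA: multi-exon coding, + strand
    start = 50_000
    e1, e2, e3 = j(7000, 9000), j(7000, 9000), j(7000, 9000)
    i1, i2 = j(9000, 12_000), j(9000, 12_000)
    b1 = (start, start + e1)
    b2 = (b1[1] + i1, b1[1] + i1 + e2)
    b3 = (b2[1] + i2, b2[1] + i2 + e3)
    # thick span: starts inside exon 1, ends inside exon 3 -> real UTR pieces
    thick = (b1[0] + j(2000, 3000), b3[1] - j(2000, 3000))
    models.append(
        TranscriptModel("chrA", b1[0], b3[1], "tx_multi_plus", "+", thick[0], thick[1], (b1, b2, b3))
    )

    # chrA: single-exon fully coding transcript, + strand, far downstream
    s2 = b3[1] + 80_000
    L2 = j(9000, 11_000)
    models.append(
        TranscriptModel("chrA", s2, s2 + L2, "tx_single_cds", "+", s2, s2 + L2, ((s2, s2 + L2),))
    )

    # chrB: non-coding two-exon transcript, + strand
    s3 = 50_000
    n1, n2 = j(5500, 7000), j(5500, 7000)
    gap = j(9000, 12_000)
    nb1 = (s3, s3 + n1)
    nb2 = (nb1[1] + gap, nb1[1] + gap + n2)
    models.append(
        TranscriptModel("chrB", nb1[0], nb2[1], "tx_noncoding", "+", s3, s3, (nb1, nb2))
    )

    # chrB: minus-strand multi-exon coding transcript
    s4 = nb2[1] + 80_000
    m1, m2 = j(7000, 9000), j(7000, 9000)
    mi = j(9000, 12_000)
    mb1 = (s4, s4 + m1)
    mb2 = (mb1[1] + mi, mb1[1] + mi + m2)
    mthick = (mb1[0] + j(2000, 3000), mb2[1] - j(2000, 3000))
    models.append(
        TranscriptModel("chrB", mb1[0], mb2[1], "tx_multi_minus", "-", mthick[0], mthick[1], (mb1, mb2))
    )

    bed_text = "\n".join(bed12_line(tx) for tx in models) + "\n"
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write(bed_text)
    return bed_text, models


# ---------------------------------------------------------------------------
# alignment simulation


@dataclass
class _Fragment:
    """One planted fragment: records plus its planted tag categories."""

    qname: str
    records: list[AlignmentRecord]
    tag_cats: list[str | None]  # per usable-read tag; None = unassigned
    kind: str  # "pair" | "orphan" | "unmapped"
    qc_fail: bool = False


def _derived_pieces(models: Sequence[TranscriptModel]):
    exonic, introns = [], []
    annotated: dict[str, list[tuple[int, int]]] = {}
    for tx in models:
        for iv in derive_regions(tx):
            annotated.setdefault(iv.chrom, []).append((iv.start, iv.end))
            if iv.category in EXONIC_CATEGORIES:
                exonic.append(iv)
            elif iv.category is RegionCategory.INTRON:
                introns.append(iv)
    return exonic, introns, annotated


def _deserts(
    annotated: dict[str, list[tuple[int, int]]],
    references: Sequence[tuple[str, int]],
    min_len: int = 20_000,
):
    out = []
    for chrom, chrom_len in references:
        ivs = sorted(annotated.get(chrom, []))
        cursor = 1000
        for s, e in ivs:
            if s - cursor >= min_len:
                out.append((chrom, cursor, s - 100))
            cursor = max(cursor, e)
        if chrom_len - 1000 - cursor >= min_len:
            out.append((chrom, cursor + 100, chrom_len - 1000))
    return out


def _junctions(models: Sequence[TranscriptModel], read_len: int):
    """Splice junctions where both flanking exonic pieces are long enough
    and single-category around the junction edges."""
    out = []
    for tx in models:
        pieces = [iv for iv in derive_regions(tx) if iv.category in EXONIC_CATEGORIES]
        for (bs1, be1), (bs2, be2) in zip(tx.blocks, tx.blocks[1:]):
            left = next((p for p in pieces if p.start <= be1 - read_len and p.end == be1), None)
            right = next((p for p in pieces if p.start == bs2 and p.end >= bs2 + 3 * read_len), None)
            if left is not None and right is not None:
                out.append((tx.chrom, be1, bs2, left.category.value, right.category.value, right.end))
    return out


def _pair_flags(read2: bool, reverse: bool, mate_reverse: bool, **kw) -> FlagSet:
    return FlagSet(
        paired=True,
        proper_pair=kw.pop("proper_pair", True),
        reverse=reverse,
        mate_reverse=mate_reverse,
        first_in_pair=not read2,
        second_in_pair=read2,
        **kw,
    )


def simulate_alignments(
    spec: SimulationSpec,
    models: Sequence[TranscriptModel],
    out_path: str | None = None,
) -> tuple[list[AlignmentRecord], TruthTable]:
    """Plant a dataset with exact read-type composition; return its truth.

    The returned records are coordinate-sorted, duplicate-UNMARKED (the
    pipeline under test does the marking), with unplaced unmapped pairs at
    the end.  If ``out_path`` is given the records are also written there
    (SAM or BAM by extension).

    Raises ValueError when the spec is infeasible for the model, e.g.
    exonic reads requested but no exonic region is long enough.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length

    references = _references(models)
    exonic_pieces, intron_pieces, annotated = _derived_pieces(models)
    deserts = _deserts(annotated, references)
    min_piece = 3 * L + 20
    exonic_pieces = [p for p in exonic_pieces if len(p) >= min_piece]
    intron_pieces = [p for p in intron_pieces if len(p) >= min_piece]
    junctions = _junctions(models, L)

    # --- exact planted counts -------------------------------------------
    n = spec.n_pairs
    n_unmapped = math.floor(n * spec.unmapped_frac)
    n_orphan = min(math.floor(n * spec.orphan_frac), n - n_unmapped)
    n_full = n - n_unmapped - n_orphan
    n_dup_full = math.floor(n_full * spec.duplicate_frac)
    n_uniq_full = n_full - n_dup_full
    n_nonex = math.floor(n_uniq_full * spec.nonexonic_frac)
    n_exonic_uniq = n_uniq_full - n_nonex
    n_qc = min(math.floor(n_uniq_full * spec.qc_fail_frac), n_exonic_uniq)
    n_spliced = math.floor((n_exonic_uniq - n_qc) * spec.splice_prob)
    n_orphan_dup = math.floor(n_orphan * spec.duplicate_frac)
    n_orphan_uniq = n_orphan - n_orphan_dup

    if (n_exonic_uniq > 0 or n_orphan_uniq > 0) and not exonic_pieces:
        raise ValueError("exonic reads requested but the model has no usable exon region")
    if n_spliced > 0 and not junctions:
        raise ValueError("spliced reads requested but the model has no usable junction")
    if n_nonex > 0 and not (intron_pieces or deserts):
        raise ValueError("non-exonic reads requested but no intron/desert available")

    used_pair_sigs: set[tuple] = set()
    used_orphan_sigs: set[tuple] = set()
    ref_rank = {name: i for i, (name, _) in enumerate(references)}

    def _weighted_piece(pieces):
        w = np.array([len(p) for p in pieces], dtype=float)
        return pieces[int(rng.choice(len(pieces), p=w / w.sum()))]

    def plant_pair(qname: str, piece, qc: bool, cat: str | None) -> _Fragment:
        """Unspliced FR pair wholly inside one region piece, unique signature."""
        if isinstance(piece, GenomicInterval):
            chrom, start, end = piece.chrom, piece.start, piece.end
        else:
            chrom, (start, end) = piece
        max_flen = min(450, end - start)
        for _ in range(200):
            flen = int(rng.integers(L, max_flen + 1)) if max_flen > L else L
            pos1 = int(rng.integers(start, end - flen + 1))
            end2 = pos1 + flen  # exclusive
            sig = (chrom, pos1, chrom, end2 - 1)
            if sig not in used_pair_sigs:
                break
        else:
            raise ValueError("could not find a unique fragment position; region too crowded")
        used_pair_sigs.add(sig)
        pos2 = end2 - L
        r1 = AlignmentRecord(
            qname=qname,
            flags=_pair_flags(read2=False, reverse=False, mate_reverse=True, qc_fail=qc),
            ref=chrom, pos=pos1, mapq=60, cigar=(("M", L),),
            mate_ref=chrom, mate_pos=pos2, tlen=flen,
        )
        r2 = AlignmentRecord(
            qname=qname,
            flags=_pair_flags(read2=True, reverse=True, mate_reverse=False, qc_fail=qc),
            ref=chrom, pos=pos2, mapq=60, cigar=(("M", L),),
            mate_ref=chrom, mate_pos=pos1, tlen=-flen,
        )
        cats = [] if qc else [cat, cat]
        return _Fragment(qname, [r1, r2], cats, "pair", qc_fail=qc)

    def plant_spliced(qname: str, junc) -> _Fragment:
        chrom, left_end, right_start, lcat, rcat, right_piece_end = junc
        gap = right_start - left_end
        for _ in range(200):
            x = int(rng.integers(20, L - 19))  # bases on the left exon
            pos1 = left_end - x
            seg2_len = L - x
            lo = right_start + seg2_len
            hi = right_piece_end - L
            if lo > hi:
                continue
            pos2 = int(rng.integers(lo, hi + 1))
            end2 = pos2 + L
            sig = (chrom, pos1, chrom, end2 - 1)
            if sig not in used_pair_sigs:
                break
        else:
            raise ValueError("could not place a unique spliced fragment")
        used_pair_sigs.add(sig)
        r1 = AlignmentRecord(
            qname=qname,
            flags=_pair_flags(read2=False, reverse=False, mate_reverse=True),
            ref=chrom, pos=pos1, mapq=60,
            cigar=(("M", x), ("N", gap), ("M", seg2_len)),
            mate_ref=chrom, mate_pos=pos2, tlen=end2 - pos1,
        )
        r2 = AlignmentRecord(
            qname=qname,
            flags=_pair_flags(read2=True, reverse=True, mate_reverse=False),
            ref=chrom, pos=pos2, mapq=60, cigar=(("M", L),),
            mate_ref=chrom, mate_pos=pos1, tlen=-(end2 - pos1),
        )
        return _Fragment(qname, [r1, r2], [lcat, rcat, rcat], "pair")

    def plant_orphan(qname: str, piece) -> _Fragment:
        start, end, chrom = piece.start, piece.end, piece.chrom
        for _ in range(200):
            pos1 = int(rng.integers(start, end - L + 1))
            sig = (chrom, pos1)
            if sig not in used_orphan_sigs:
                break
        else:
            raise ValueError("could not place a unique orphan")
        used_orphan_sigs.add(sig)
        r1 = AlignmentRecord(
            qname=qname,
            flags=_pair_flags(read2=False, reverse=False, mate_reverse=False,
                              proper_pair=False, mate_unmapped=True),
            ref=chrom, pos=pos1, mapq=60, cigar=(("M", L),),
            mate_ref=None, mate_pos=None, tlen=0,
        )
        r2 = AlignmentRecord(
            qname=qname,
            flags=FlagSet(paired=True, unmapped=True, second_in_pair=True),
        )
        return _Fragment(qname, [r1, r2], [piece.category.value], "orphan")

    def clip_copy(frag: _Fragment, qname: str) -> _Fragment:
        """Copy of a fragment whose ends keep their unclipped 5' positions.

        The forward mate gains a leading soft clip with a compensating
        position shift; the reverse mate gains a trailing soft clip with a
        shortened match, leaving the rightmost unclipped coordinate fixed.
        """
        c = int(rng.integers(3, 16))
        out = []
        for rec in frag.records:
            if not rec.is_mapped:
                out.append(replace(rec, qname=qname))
                continue
            ops = rec.cigar
            if len(ops) != 1 or ops[0][0] != "M" or ops[0][1] <= c + 10:
                out.append(replace(rec, qname=qname))  # spliced mate: exact copy
                continue
            if not rec.flags.reverse:
                rec2 = replace(rec, qname=qname, pos=rec.pos + c,
                               cigar=(("S", c), ("M", L - c)))
            else:
                rec2 = replace(rec, qname=qname, cigar=(("M", L - c), ("S", c)),
                               pos=rec.pos)
            out.append(rec2)
        # keep mate pointers consistent after any position shift
        if len(out) == 2 and all(r.is_mapped for r in out):
            out = [
                replace(out[0], mate_pos=out[1].pos),
                replace(out[1], mate_pos=out[0].pos),
            ]
        return _Fragment(qname, out, list(frag.tag_cats), frag.kind, frag.qc_fail)

    fragments: list[_Fragment] = []
    serial = 0

    def next_qname(prefix: str) -> str:
        nonlocal serial
        serial += 1
        return f"{prefix}{serial:08d}"

    # unique exonic full pairs (spliced + unspliced) -----------------------
    for i in range(n_exonic_uniq - n_qc):
        if i < n_spliced:
            junc = junctions[int(rng.integers(len(junctions)))]
            fragments.append(plant_spliced(next_qname("sf"), junc))
        else:
            piece = _weighted_piece(exonic_pieces)
            fragments.append(plant_pair(next_qname("ef"), piece, False, piece.category.value))
    # QC-fail pairs (placed exonic; contribute no tags)
    for _ in range(n_qc):
        piece = _weighted_piece(exonic_pieces)
        fragments.append(plant_pair(next_qname("qf"), piece, True, None))
    # non-exonic unique pairs: alternate intron / desert
    for i in range(n_nonex):
        if intron_pieces and (i % 2 == 0 or not deserts):
            piece = _weighted_piece(intron_pieces)
            fragments.append(plant_pair(next_qname("nf"), piece, False, RegionCategory.INTRON.value))
        else:
            chrom, s, e = deserts[int(rng.integers(len(deserts)))]
            fragments.append(plant_pair(next_qname("df"), (chrom, (s, e)), False, None))
    # duplicates: byte-equivalent or clip-variant copies of unique non-QC pairs
    templates = [f for f in fragments if f.kind == "pair" and not f.qc_fail]
    if n_dup_full > 0 and not templates:
        raise ValueError("duplicate pairs requested but no unique template pair exists")
    for _ in range(n_dup_full):
        t = templates[int(rng.integers(len(templates)))]
        qname = next_qname("dp")
        if rng.random() < spec.clip_prob:
            fragments.append(replace(clip_copy(t, qname), tag_cats=[]))
        else:
            recs = [replace(r, qname=qname) for r in t.records]
            fragments.append(_Fragment(qname, recs, [], t.kind))
    # orphans: unique + duplicate copies (copies fall back to unique
    # placement if no template exists, preserving the pair total)
    orphan_templates: list[_Fragment] = []
    actual_orphan_dup = 0
    for _ in range(n_orphan_uniq):
        piece = _weighted_piece(exonic_pieces)
        frag = plant_orphan(next_qname("of"), piece)
        orphan_templates.append(frag)
        fragments.append(frag)
    for _ in range(n_orphan_dup):
        if orphan_templates:
            t = orphan_templates[int(rng.integers(len(orphan_templates)))]
            qname = next_qname("od")
            recs = [replace(r, qname=qname) for r in t.records]
            fragments.append(_Fragment(qname, recs, [], "orphan"))
            actual_orphan_dup += 1
        else:
            frag = plant_orphan(next_qname("of"), _weighted_piece(exonic_pieces))
            orphan_templates.append(frag)
            fragments.append(frag)
    n_orphan_uniq = n_orphan - actual_orphan_dup
    # fully unmapped pairs
    for _ in range(n_unmapped):
        qname = next_qname("uf")
        r1 = AlignmentRecord(qname=qname, flags=FlagSet(paired=True, unmapped=True, mate_unmapped=True, first_in_pair=True))
        r2 = AlignmentRecord(qname=qname, flags=FlagSet(paired=True, unmapped=True, mate_unmapped=True, second_in_pair=True))
        fragments.append(_Fragment(qname, [r1, r2], [], "unmapped"))

    # --- truth ------------------------------------------------------------
    truth = TruthTable(n_pairs=n)
    truth.unmapped_reads = 2 * n_unmapped + n_orphan
    truth.mapped_reads = 2 * n_full + n_orphan
    truth.qc_fail_reads = 2 * n_qc
    truth.duplicate_reads = 2 * n_dup_full + actual_orphan_dup
    truth.usable_reads = truth.mapped_reads - truth.qc_fail_reads - truth.duplicate_reads
    truth.duplicate_fragments = n_dup_full + actual_orphan_dup
    for frag in fragments:
        if frag.qc_fail:
            continue
        for cat in frag.tag_cats:
            truth.add_tag(cat)

    # --- coordinate sort and output --------------------------------------
    records = [rec for frag in fragments for rec in frag.records]
    records.sort(
        key=lambda rec: (1, 0, 0) if rec.ref is None else (0, ref_rank[rec.ref], rec.pos)
    )

    if out_path is not None:
        write_alignments(records, out_path, make_header(references))
    return records, truth


# ---------------------------------------------------------------------------
# survey-table simulation

#: Marginal fraction distributions matching the survey's printed
#: median/IQR compositions, and the log-normal depth scale.
SURVEY_MARGINALS = {
    "unmapped": (1.3, 30.0),   # Beta; median ~3%, IQR ~2-6%
    "dup": (1.4, 3.4),         # Beta; median ~26%, IQR ~14-42%
    "nonexonic": (2.2, 6.2),   # Beta; median ~24%, IQR ~15-35%
    "depth_median_pairs": 61e6,
    "depth_sigma": 0.5,
}


def simulate_survey_table(
    n_datasets: int = 2179,
    n_cohorts: int = 48,
    spearman_depth_dup: float = 0.52,
    cohort_effect_var: float = 0.15,
    seed: int = 0,
):
    """Simulate a cohort survey table with planted rank dependence.

    Depth and duplicate fraction share a Gaussian copula whose latent
    Pearson correlation is chosen so the population Spearman equals
    ``spearman_depth_dup`` (r = 2 sin(pi * rho / 6)).  A per-cohort random
    effect with variance ``cohort_effect_var`` loads on both latents (and,
    independently, on the unmapped and non-exonic latents), producing
    cohort-level location shifts while keeping every marginal exactly
    standard normal, hence the Beta/log-normal marginals exact.

    Returns (DataFrame of DatasetRecord columns incl. fractions, dict of
    planted parameters).
    """
    import pandas as pd

    from .survey import DatasetRecord, compute_fractions, records_to_frame

    if not -1 < spearman_depth_dup < 1:
        raise ValueError("spearman_depth_dup must be in (-1, 1)")
    if not 0 <= cohort_effect_var < 1:
        raise ValueError("cohort_effect_var must be in [0, 1)")
    rng = np.random.default_rng(seed)
    r = 2.0 * math.sin(math.pi * spearman_depth_dup / 6.0)
    a2 = cohort_effect_var
    if abs(r) < a2:
        a2 = abs(r) * 0.5  # keep the idiosyncratic correlation well-defined
    # the shared cohort effect loads with the sign of the target so the
    # idiosyncratic correlation stays in [-1, 1]
    s = 1.0 if r >= 0 else -1.0
    ru = (r - s * a2) / (1.0 - a2)
    a = math.sqrt(a2)
    b = math.sqrt(1.0 - a2)

    # cohort assignment: heterogeneous sizes via Dirichlet weights
    weights = rng.dirichlet(np.full(n_cohorts, 0.8))
    cohort_of = rng.choice(n_cohorts, size=n_datasets, p=weights)

    c_depth_dup = rng.standard_normal(n_cohorts)
    c_unmapped = rng.standard_normal(n_cohorts)
    c_nonex = rng.standard_normal(n_cohorts)

    u1 = rng.standard_normal(n_datasets)
    u2 = ru * u1 + math.sqrt(1 - ru * ru) * rng.standard_normal(n_datasets)
    z_depth = a * c_depth_dup[cohort_of] + b * u1
    z_dup = s * a * c_depth_dup[cohort_of] + b * u2
    z_unm = a * c_unmapped[cohort_of] + b * rng.standard_normal(n_datasets)
    z_nex = a * c_nonex[cohort_of] + b * rng.standard_normal(n_datasets)

    m = SURVEY_MARGINALS
    depth = np.rint(
        np.exp(np.log(m["depth_median_pairs"]) + m["depth_sigma"] * z_depth)
    ).astype(np.int64)
    dup_f = stats.beta.ppf(stats.norm.cdf(z_dup), *m["dup"])
    unm_f = stats.beta.ppf(stats.norm.cdf(z_unm), *m["unmapped"])
    nex_f = stats.beta.ppf(stats.norm.cdf(z_nex), *m["nonexonic"])

    records = []
    for i in range(n_datasets):
        total = int(max(depth[i], 1))
        mapped = int(round(total * (1 - unm_f[i])))
        dup = int(round(mapped * dup_f[i]))
        mend = int(round((mapped - dup) * (1 - nex_f[i])))
        records.append(
            compute_fractions(
                DatasetRecord(
                    dataset_id=f"SYN{i:05d}",
                    cohort=f"cohort{cohort_of[i]:02d}",
                    total_pairs=total,
                    mapped_pairs=mapped,
                    duplicate_pairs=dup,
                    mend_pairs=mend,
                )
            )
        )
    frame = records_to_frame(records)
    planted = {
        "spearman_depth_dup": spearman_depth_dup,
        "latent_pearson": r,
        "cohort_effect_var": a2,
        "marginals": dict(m),
        "n_datasets": n_datasets,
        "n_cohorts": n_cohorts,
        "seed": seed,
    }
    return frame, planted
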