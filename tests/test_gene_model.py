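"""Gene-model parsing, region derivation and interval indexing."""

import pytest
from hypothesis import given, settings, strategies as st

from mendqc.gene_model import (
    BedParseError,
    GenomicInterval,
    RegionCategory,
    TranscriptModel,
    build_region_index,
    derive_regions,
    parse_bed12,
)

C = RegionCategory


def _by_cat(intervals):
    out = {}
    for iv in intervals:
        out.setdefault(iv.category, []).append((iv.start, iv.end))
    return out


class TestParseBed12:
    def test_blocks_and_thick_converted_to_absolute(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t100\t1000\ttx1\t0\t+\t200\t900\t0\t2\t100,100\t0,800\n")
        (tx,) = parse_bed12(str(bed))
        assert tx.blocks == ((100, 200), (900, 1000))
        assert (tx.thick_start, tx.thick_end) == (200, 900)
        assert tx.strand == "+"

    def test_trailing_commas_tolerated(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t0\t300\ttx\t0\t-\t0\t300\t0\t2\t100,100,\t0,200,\n")
        (tx,) = parse_bed12(str(bed))
        assert tx.blocks == ((0, 100), (200, 300))

    def test_empty_file_gives_empty_list(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert parse_bed12(str(bed)) == []

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\t1000\ttx1\t0\t+\t200\t900\t0\t2\t100,100",  # 11 columns
            "chr1\t100\t1000\ttx1\t0\t+\t200\t900\t0\t3\t100,100\t0,800",  # count mismatch
            "chr1\t100\t1000\ttx1\t0\t+\t50\t900\t0\t2\t100,100\t0,800",  # thick outside
        ],
    )
    def test_malformed_line_raises_with_line_number(self, tmp_path, line):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t100\tok\t0\t+\t0\t100\t0\t1\t100\t0\n" + line + "\n")
        with pytest.raises(BedParseError, match="line 2"):
            parse_bed12(str(bed))


class TestDeriveRegions:
    def test_utr_only_transcript(self, coding_tx):
        cats = _by_cat(derive_regions(coding_tx))
        assert C.CDS_EXON not in cats
        assert cats[C.UTR5_EXON] == [(100, 200)]
        assert cats[C.UTR3_EXON] == [(900, 1000)]
        assert cats[C.INTRON] == [(200, 900)]

    def test_minus_strand_swaps_utrs(self, coding_tx):
        minus = TranscriptModel(
            chrom=coding_tx.chrom, tx_start=coding_tx.tx_start,
            tx_end=coding_tx.tx_end, name="tx1m", strand="-",
            thick_start=coding_tx.thick_start, thick_end=coding_tx.thick_end,
            blocks=coding_tx.blocks,
        )
        cats = _by_cat(derive_regions(minus))
        assert cats[C.UTR5_EXON] == [(900, 1000)]
        assert cats[C.UTR3_EXON] == [(100, 200)]

    def test_single_block_fully_coding(self):
        tx = TranscriptModel("chr1", 5000, 6000, "s", "+", 5000, 6000, ((5000, 6000),))
        cats = _by_cat(derive_regions(tx))
        assert cats[C.CDS_EXON] == [(5000, 6000)]
        assert C.UTR5_EXON not in cats and C.UTR3_EXON not in cats
        assert C.INTRON not in cats

    def test_noncoding_blocks_emitted_as_noncoding_exon(self, noncoding_tx):
        cats = _by_cat(derive_regions(noncoding_tx))
        assert cats[C.NONCODING_EXON] == [(500, 1200), (2000, 2500)]
        assert C.CDS_EXON not in cats

    def test_flanks_nested_and_clipped_at_zero(self):
        tx = TranscriptModel("chr1", 3000, 4000, "f", "+", 3000, 4000, ((3000, 4000),))
        cats = _by_cat(derive_regions(tx))
        assert cats[C.TSS_UP_1K] == [(2000, 3000)]
        assert cats[C.TSS_UP_5K] == [(0, 3000)]      # clipped at 0
        assert cats[C.TSS_UP_10K] == [(0, 3000)]
        assert cats[C.TES_DOWN_1K] == [(4000, 5000)]
        assert cats[C.TES_DOWN_10K] == [(4000, 14000)]

    def test_exon_and_intron_lengths_conserve_span(self, rich_tx):
        cats = _by_cat(derive_regions(rich_tx))
        genic = (C.CDS_EXON, C.UTR5_EXON, C.UTR3_EXON, C.NONCODING_EXON)
        exon_len = sum(e - s for c in genic for s, e in cats.get(c, []))
        intron_len = sum(e - s for s, e in cats.get(C.INTRON, []))
        assert exon_len == rich_tx.block_length()
        assert exon_len + intron_len == rich_tx.tx_end - rich_tx.tx_start

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_strand_symmetry_properties(self, data):
        """Flipping the strand in place swaps UTR5<->UTR3 and TSS<->TES
        categories at the same coordinates; mirroring the coordinates as
        well restores the original categories (the transcript then reads
        identically in transcription order)."""
        n_blocks = data.draw(st.integers(1, 4))
        # keep everything >= 10 kb from zero so no flank clips on either side
        edges = sorted(
            data.draw(
                st.lists(st.integers(20_000, 25_000), min_size=2 * n_blocks,
                         max_size=2 * n_blocks, unique=True)
            )
        )
        blocks = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_blocks))
        span = (blocks[0][0], blocks[-1][1])
        t0 = data.draw(st.integers(span[0], span[1]))
        t1 = data.draw(st.integers(t0, span[1]))
        tx = TranscriptModel("c", span[0], span[1], "t", "+", t0, t1, blocks)
        fwd = {(iv.category, iv.start, iv.end) for iv in derive_regions(tx)}
        swap = {C.UTR5_EXON: C.UTR3_EXON, C.UTR3_EXON: C.UTR5_EXON,
                C.TSS_UP_1K: C.TES_DOWN_1K, C.TES_DOWN_1K: C.TSS_UP_1K,
                C.TSS_UP_5K: C.TES_DOWN_5K, C.TES_DOWN_5K: C.TSS_UP_5K,
                C.TSS_UP_10K: C.TES_DOWN_10K, C.TES_DOWN_10K: C.TSS_UP_10K}

        # strand flip in place: swapped categories, same coordinates
        flipped = TranscriptModel("c", span[0], span[1], "t", "-", t0, t1, blocks)
        assert {(iv.category, iv.start, iv.end) for iv in derive_regions(flipped)} == {
            (swap.get(cat, cat), s, e) for cat, s, e in fwd
        }

        # mirror + flip: same categories at mirrored coordinates
        m = 50_000
        mirror_blocks = tuple(sorted((m - e, m - s) for s, e in blocks))
        mtx = TranscriptModel(
            "c", m - span[1], m - span[0], "t", "-", m - t1, m - t0, mirror_blocks
        )
        assert {(iv.category, iv.start, iv.end) for iv in derive_regions(mtx)} == {
            (cat, m - e, m - s) for cat, s, e in fwd
        }


class TestRegionIndex:
    def test_intron_lookup(self, region_index):
        assert region_index.lookup("chr1", 2500, 2600) == {C.INTRON}

    def test_unannotated_chromosome_returns_empty(self, region_index):
        assert region_index.lookup("chrZ", 0, 1000) == set()

    def test_overlapping_transcripts_return_both_categories(self):
        a = TranscriptModel("c", 0, 3000, "a", "+", 0, 3000, ((0, 1000), (2000, 3000)))
        b = TranscriptModel("c", 0, 3000, "b", "+", 0, 3000, ((0, 3000),))
        idx = build_region_index([a, b])
        # bases in a's intron are CDS in b
        assert idx.lookup("c", 1200, 1300) == {C.CDS_EXON, C.INTRON}

    def test_empty_model_list_is_configuration_error(self):
        with pytest.raises(ValueError):
            build_region_index([])

    def test_duplicate_transcript_rows_collapse(self, rich_tx):
        once = build_region_index([rich_tx])
        twice = build_region_index([rich_tx, rich_tx])
        for start in range(900, 9200, 37):
            assert once.lookup("chr1", start, start + 10) == twice.lookup(
                "chr1", start, start + 10
            )

    def test_lookup_agrees_with_per_base_scan(self, rich_tx, noncoding_tx):
        """Index lookups must match a brute-force scan over every derived
        interval on a <=10 kb fixture."""
        models = [rich_tx, noncoding_tx]
        idx = build_region_index(models)
        all_ivs: list[GenomicInterval] = []
        for tx in models:
            all_ivs.extend(derive_regions(tx))
        import random

        rnd = random.Random(42)
        for _ in range(300):
            tx = rnd.choice(models)
            s = rnd.randrange(0, 10_000)
            e = s + rnd.randrange(1, 200)
            brute = {
                iv.category
                for iv in all_ivs
                if iv.chrom == tx.chrom and iv.start < e and s < iv.end
            }
            assert idx.lookup(tx.chrom, s, e) == brute
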