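# Methods

## The MEND metric

A bulk RNA-seq dataset's usable depth is taken to be its number of MEND
reads: reads that are **M**apped, fall in **E**xonic regions, and are
**N**ot **D**uplicates. The computation proceeds in three stages over a
coordinate-sorted, paired-end alignment file and a BED12 gene model.

**1. Duplicate marking.** Each fragment is reduced to a signature: the
(reference, unclipped 5′ coordinate, strand) of each mapped end, in
canonical (sorted) order. The unclipped 5′ coordinate backs soft and
hard clips out of the alignment position, so a clipped copy of a
fragment collides with its unclipped twin; canonical ordering makes the
signature independent of which mate is encountered first. Within a
signature group the first-encountered fragment in file order stays
unmarked; every later one has the duplicate flag (0x400) set on both
mates. Fragments with exactly one mapped end ("orphans") form
single-end signatures and are compared only against other orphans; pairs
with both mates unmapped are never marked. There is no quality-based
survivor selection and no optical-duplicate distinction: the metric does
not separate PCR from optical duplicates, and first-wins makes marking
deterministic for a fixed file. Marking ignores pre-existing duplicate
flags, which makes it idempotent. Signatures are held in an in-memory
map; the tool targets desk-scale files, and no disk-backed two-pass mode
is provided.

**2. Read-type classification.** Every record receives exactly one
label, tested in precedence order: UNMAPPED, SECONDARY, SUPPLEMENTARY,
QC_FAIL, DUPLICATE, USABLE. Secondary and supplementary alignments sit
in diagnostic buckets outside the unmapped/mapped split so that
multi-mapping reads are never multiply counted; QC-fail records are
excluded from both the duplicate and usable pools but reported. The
hierarchy conservation sums (unmapped + mapped = primary records;
QC-fail + duplicates + usable = mapped; assigned + unassigned tags =
total tags) are asserted on every run.

**3. Tag counting and the MEND estimate.** Each usable read is split at
CIGAR `N` operations into tags — contiguous reference segments touching
one exon each; deletions (`D`) extend a tag, insertions and clips
consume no reference. Each tag is assigned the highest-precedence region
category it overlaps: CDS exon > 5′UTR exon > 3′UTR exon > non-coding
exon > intron > TSS ±1k > TES ±1k > 5k > 10k flanks. The MEND estimate
converts exonic tag counts back to reads through the dataset-wide ratio:

    reads_per_tag = usable_reads / total_tags
    mend_reads    = round(exonic_tags × reads_per_tag)

`reads_per_tag` uses usable reads and tags *from usable reads only*;
mixing excluded populations into either side would bias the ratio.
Tags are assigned individually (a read straddling categories contributes
each tag separately). All depth figures are reported both in reads and
in pairs; pair counts halve read counts and truncate on odd values.
All 0/0 fractions are defined as 0.

## Gene-model regions

BED12 transcripts are split into categorized half-open intervals:
CDS exon pieces (block ∩ thick span), UTR exon pieces with 5′/3′
assignment following transcription order on the strand, introns (gaps
between blocks), and nested flanking windows (1 kb ⊂ 5 kb ⊂ 10 kb)
upstream of the TSS and downstream of the TES, clipped at coordinate 0.
All coordinates are 0-based half-open internally; conversion happens
only inside the SAM/BAM layer (pysam). Redundant annotation rows
(identical chrom/span/strand/blocks) are collapsed before indexing.

**Non-coding transcripts.** A BED12 record with `thickStart ==
thickEnd` has no CDS. Its exon blocks are indexed under a distinct
NONCODING_EXON category that **counts as exonic** for the MEND estimate
by default, because reads on non-coding genes contribute to expression
quantification in inclusive gene models (tens of thousands of genes,
many non-coding); excluding them would systematically undercount usable
depth. The `--coding-only` flag (or `estimate_mend(...,
coding_only=True)`) restricts the sum to CDS+UTR tags for strict
compatibility with CDS-centric summaries. This treatment is a design
choice of this package; reference tools do not document their
precedence for non-coding exons.

## Survey statistics

Survey tables carry one row per dataset with pair counts (total, mapped,
duplicate, MEND) from which the hierarchy fractions are derived:
unmapped/total, duplicates/mapped, 1 − MEND/(mapped − duplicates), and
MEND/total. Unmapped counts at the survey level are `total − mapped`
(the aligner-log convention), while the alignment pipeline counts
unmapped records directly; both populate the same record type.

Quartiles use linear interpolation between order statistics (the common
default of mainstream numerical environments); `--quantile-method
lower|nearest` are provided because published IQRs do not always state
their interpolation rule. Censuses count rows satisfying *strict*
threshold predicates, matching how such counts are usually printed
(">50%" excludes exactly 50%). The depth–duplicate association is
Spearman's rank correlation (mean ranks on ties, via scipy); depth is
measured in total pairs. The depth-recommendation arithmetic converts a
mapped-read guideline into MEND reads:
`(mapped_target + typical_unmapped) × mend_fraction_of_total`.

## Synthetic data

### Alignment-level generator

`simulate_gene_model` lays out four transcripts over two chromosomes —
a plus-strand multi-exon coding gene with real UTR pieces, a single-exon
fully coding gene, a two-exon non-coding gene, and a minus-strand
multi-exon coding gene — with exon sizes jittered by the seed (7–9 kb
exons, 9–12 kb introns). Transcripts are ≥ 60 kb apart so 10 kb flanks
never reach a neighbour, and every chromosome retains an unannotated
desert ≥ 20 kb for placing intergenic reads.

`simulate_alignments` plants **exact** counts — floors of the target
fractions, not Bernoulli draws — so the truth table is an exact oracle
rather than a statistical one:

- `⌊n·unmapped_frac⌋` pairs with both mates unmapped;
- a small orphan sub-population (`orphan_frac`, default 2%) with one
  mapped, one unmapped mate, exercising single-end signatures;
- of mapped fragments, `⌊·duplicate_frac⌋` byte-equivalent copies of
  already-planted fragments, a `clip_prob` share of them as soft-clip
  variants whose compensating position shifts preserve both unclipped
  5′ ends;
- of unique mapped pairs, `⌊·nonexonic_frac⌋` placed wholly inside
  introns (alternating with deserts), the rest wholly inside single
  region pieces of exons, with a `splice_prob` share spliced across an
  exon junction with a correct `N` CIGAR;
- optional QC-fail pairs (`qc_fail_frac`, default 0).

Uniquely planted fragments are guaranteed signature-distinct (position
draws are retried on collision), so the planted duplicate count is
exactly the number of marked fragments. Reads are 101 bases (one length
per dataset, the typical read length of the surveyed data); fragment
lengths are uniform on [read_length, 450]. The default composition —
3% unmapped, 27% duplicates, 25% non-exonic — mirrors the median
composition observed in large heterogeneous tumor cohort surveys.

What the generator does **not** emulate: sequence content, base
qualities, alignment errors, expression-level structure, multi-mapping
(secondary/supplementary records), or chimeric reads. Passing the
equivalence suite therefore demonstrates that the counting logic is
exact on flag-correct input, not that upstream alignment artifacts are
handled; on real data the numbers inherit the aligner's and gene
model's choices.

### Survey-table generator

`simulate_survey_table` draws, per dataset: total depth log-normal
(median 61 M pairs, σ = 0.5), and Beta-distributed fractions — unmapped
Beta(1.3, 30) (median ≈ 3%), duplicate Beta(1.4, 3.4) (median ≈ 26%,
IQR ≈ 14–42%), non-exonic Beta(2.2, 6.2) (median ≈ 24%) — chosen once
to match the median/IQR compositions reported for large heterogeneous
tumor surveys. Depth and duplicate fraction share a Gaussian copula
whose latent Pearson correlation r = 2·sin(πρ/6) yields the requested
population Spearman ρ (default 0.52). A per-cohort normal effect
(variance 0.15) loads on both coupled latents and, independently, on
the unmapped and non-exonic latents; because each latent stays standard
normal marginally, cohort structure is added without distorting the
Beta/log-normal marginals or the planted ρ. Counts are rounded to
integers satisfying the count hierarchy. Dataset-to-cohort assignment
uses Dirichlet(0.8) weights over 48 cohorts, giving realistically
unequal cohort sizes.

## Numerical choices and degenerate inputs

- `mend_reads` rounds half away from zero; `mend_pairs` truncates the
  halved read count (published conventions do not state the rounding of
  pair halving; truncation is documented here and used consistently).
- Empty datasets, all-unmapped datasets and zero-exonic datasets report
  zeros rather than erroring (0/0 := 0).
- A mapped primary record whose mate is absent from the stream is
  treated as an orphan with a warning.
- Duplicate marking raises on templates with more than two mapped
  primary records (malformed input).
- Interval index lookups outside all annotation return the empty set;
  such tags are UNASSIGNED and count against the exonic fraction.

## Problem sizes

The equivalence grid in the test suite spans 10³–10⁵ pairs per dataset
across 20 composition points (fractions 0–0.9), a scale at which the
whole suite completes in well under a minute while exercising every
planting mechanism; the survey recovery checks use the full 2,179 × 48
survey geometry. These sizes are the package's chosen test conditions,
not limits of the method.

## Known limitations

- BAM/SAM only (no CRAM); GTF/GFF gene models must be converted to
  BED12 externally.
- Duplicate marking holds all signatures in memory.
- The MEND count is conditional on the aligner's mapping policy and the
  gene model's inclusiveness; the same reads under a stricter
  multi-mapping limit or a smaller gene model yield fewer MEND reads.
- UMI-aware deduplication and strandedness inference are out of scope;
  duplicates are marked, never removed.
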