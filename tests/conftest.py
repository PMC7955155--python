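import pytest
from hypothesis import settings

from mendqc.gene_model import TranscriptModel, build_region_index

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def coding_tx() -> TranscriptModel:
    """Two-block plus-strand transcript whose thick span falls between the
    blocks: block 1 is entirely 5'UTR, block 2 entirely 3'UTR."""
    return TranscriptModel(
        chrom="chr1", tx_start=100, tx_end=1000, name="tx1", strand="+",
        thick_start=200, thick_end=900, blocks=((100, 200), (900, 1000)),
    )


@pytest.fixture
def rich_tx() -> TranscriptModel:
    """Three-block plus-strand transcript with UTR5/CDS/UTR3 pieces and
    two introns, on a 10 kb scale suitable for brute-force scans."""
    return TranscriptModel(
        chrom="chr1", tx_start=1000, tx_end=9000, name="rich", strand="+",
        thick_start=1500, thick_end=8200,
        blocks=((1000, 2000), (4000, 5000), (8000, 9000)),
    )


@pytest.fixture
def noncoding_tx() -> TranscriptModel:
    return TranscriptModel(
        chrom="chr2", tx_start=500, tx_end=2500, name="nc1", strand="+",
        thick_start=500, thick_end=500, blocks=((500, 1200), (2000, 2500)),
    )


@pytest.fixture
def region_index(rich_tx, noncoding_tx):
    return build_region_index([rich_tx, noncoding_tx])
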