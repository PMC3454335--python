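import numpy as np
import pytest

from exoreg.core import GeneModel, GenomicInterval, ScoreTrack, TypedExon


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_exon_gene():
    """+ strand gene: 5'UTR..CDS exon1 | CDS..3'UTR exon2 on chr1.

    Layout: exon1 [100, 160) with UTR5 [100,110) + CDS [110,160);
    exon2 [200, 260) with CDS [200,250) + UTR3 [250,260).
    CDS length = 50 + 50 = 100, not a multiple of 3 on purpose — the
    trailing partial codon exercises the 'unassigned' path.
    """
    exons = [
        TypedExon(GenomicInterval("chr1", 100, 110, "+"), "utr5"),
        TypedExon(GenomicInterval("chr1", 110, 160, "+"), "cds"),
        TypedExon(GenomicInterval("chr1", 200, 250, "+"), "cds"),
        TypedExon(GenomicInterval("chr1", 250, 260, "+"), "utr3"),
    ]
    return GeneModel("g1", "chr1", "+", exons)


@pytest.fixture
def flat_track():
    """Constant-score track covering chr1:[100,160) and [200,260)."""
    t = ScoreTrack()
    t.add_segment("chr1", 100, np.full(60, 0.5))
    t.add_segment("chr1", 200, np.full(60, 0.5))
    return t
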