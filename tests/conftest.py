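import numpy as np
import pytest

from aseview.gene_model import Exon, GeneModel, Transcript
from aseview.track_io import Junction


def make_transcript(tx_id, coords, chrom="chr1", strand="+", incomplete=False):
    exons = [Exon(chrom, s, e, transcript_ids=frozenset({tx_id}))
             for s, e in coords]
    return Transcript(tx_id, chrom, strand, exons, is_incomplete=incomplete)


def random_transcript(rng, tx_id, chrom="chr1", strand="+", n_exons=5,
                      lo=0, hi=10_000):
    """Random non-overlapping sorted exons inside [lo, hi)."""
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_exons,
                              replace=False))
    coords = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
    return make_transcript(tx_id, coords, chrom, strand)


@pytest.fixture
def cassette_gene():
    """Three meta-exons at [1000,1100), [1200,1300), [1400,1500); the middle
    one is the cassette: tx_in includes it, tx_out skips it."""
    tx_in = make_transcript(
        "tx_in", [(1000, 1100), (1200, 1300), (1400, 1500)]
    )
    tx_out = make_transcript("tx_out", [(1000, 1100), (1400, 1500)])
    return GeneModel("G1", "chr1", "+", [tx_in, tx_out])


@pytest.fixture
def cassette_junctions():
    """Annotated junctions of the cassette gene: two inclusion, one
    exclusion."""
    incl_up = Junction("chr1", 1100, 1200, "+", known=True)
    incl_down = Junction("chr1", 1300, 1400, "+", known=True)
    excl = Junction("chr1", 1100, 1400, "+", known=True)
    return incl_up, incl_down, excl


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
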