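import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exhume.formats import IsoformAlignment, IsoformRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_alignment(rows, gene="GENE"):
    """Build an IsoformAlignment from (iso_id, species, chrom, strand, score,
    aligned_string, coords) tuples; coords has one entry per non-gap residue."""
    recs = []
    M = []
    P = []
    for iso_id, species, chrom, strand, score, aligned, coords in rows:
        recs.append(IsoformRecord(iso_id, species, chrom, strand, score))
        M.append(list(aligned))
        prow = []
        it = iter(coords)
        for ch in aligned:
            prow.append(0 if ch == "-" else next(it))
        P.append(prow)
    aln = IsoformAlignment(gene, recs, np.array(M, dtype="<U1"), np.array(P, dtype=np.int64))
    aln.validate()
    return aln


@pytest.fixture
def simple_alignment():
    """Three species; species sp2 entirely lacks the middle exon (cols 5-8).

    Exon layout (columns 1-4 | 5-8 | 9-12), contiguous codons within an exon,
    large coordinate jumps between exons.
    """
    return make_alignment(
        [
            ("a1", "sp1", "c1", "+", 1, "MKVLACDEFGHI",
             [101, 104, 107, 110, 1001, 1004, 1007, 1010, 2001, 2004, 2007, 2010]),
            ("b1", "sp2", "c2", "+", 2, "MKVL----FGHI",
             [201, 204, 207, 210, 3001, 3004, 3007, 3010]),
            ("c1", "sp3", "c3", "+", None, "MRVLACDDFGHI",
             [301, 304, 307, 310, 4001, 4004, 4007, 4010, 5001, 5004, 5007, 5010]),
        ]
    )
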