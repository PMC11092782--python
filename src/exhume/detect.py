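"""Missing-exon candidate detection and search-window arithmetic.

An exon block whose column range is entirely gapped in one species' all-exon
row, while at least one other species has residues there, marks a candidate:
the exon may exist unobserved in that species' genome. The residues of each
other species over the block become query peptides (minimum 6 aa), and the
codon coordinates flanking the block bound the genomic window in which the
homolog must lie; when a flank is absent the window falls back to a fixed
25,000 nt extension from the remaining flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from exhume.collapse import AllExonAlignment
from exhume.formats import GAP, NO_COORD

logger = logging.getLogger("exhume")

#: queries shorter than this many residues are discarded
MIN_QUERY_LENGTH = 6

#: one-sided window extension (nt) when an upstream or downstream exon is absent
DEFAULT_WINDOW_PAD = 25_000


@dataclass
class QueryExonPeptide:
    """A candidate homolog's sequence taken from another species' row."""

    source_species: str
    peptide: str
    source_chrom: str
    source_strand: str
    source_start: int  # genomic interval of the source exon, 1-based inclusive
    source_end: int
    source_annotation_score: int | None = None


@dataclass
class MissingExonCandidate:
    """A (species, exon block) pair flagged for genomic search."""

    gene: str
    target_species: str
    block_index: int  # 0-based index into X
    block: tuple[int, int]  # 1-based inclusive column range (b, e)
    queries: list[QueryExonPeptide] = field(default_factory=list)


@dataclass
class SearchWindow:
    """Genomic interval (reference forward-strand coords) to search."""

    chrom: str
    strand: str
    L: int
    R: int

    @property
    def length(self) -> int:
        return self.R - self.L + 1


def build_query_peptides(
    aln: AllExonAlignment, candidate: MissingExonCandidate
) -> list[QueryExonPeptide]:
    """Collect, per non-target species, the block residues as a query peptide.

    Gaps are stripped; peptides shorter than 6 residues are discarded. The
    source genomic interval spans the full codons of the first and last block
    residues (codon middle +/- 1 nt). The annotation score attached is the
    best score among isoforms that contributed residues in the block.
    """
    b, e = candidate.block
    queries: list[QueryExonPeptide] = []
    for k, sp in enumerate(aln.species):
        if sp == candidate.target_species:
            continue
        cells = aln.C[k, b - 1 : e]
        mask = cells != GAP
        if not mask.any():
            continue
        peptide = "".join(cells[mask])
        if len(peptide) < MIN_QUERY_LENGTH:
            logger.debug(
                "%s block %d: query from %s too short (%d aa), discarded",
                aln.gene, candidate.block_index, sp, len(peptide),
            )
            continue
        coords = aln.Q[k, b - 1 : e][mask]
        queries.append(
            QueryExonPeptide(
                source_species=sp,
                peptide=peptide,
                source_chrom=aln.chrom[sp],
                source_strand=aln.strand[sp],
                source_start=int(coords.min()) - 1,
                source_end=int(coords.max()) + 1,
                source_annotation_score=_block_score(aln, k, b, e),
            )
        )
    return queries


def _block_score(aln: AllExonAlignment, k: int, b: int, e: int) -> int | None:
    scores = aln.A[k, b - 1 : e]
    scores = scores[scores > 0]
    return int(scores.min()) if scores.size else None


def find_missing_exons(aln: AllExonAlignment) -> list[MissingExonCandidate]:
    """Scan every (species, block) pair for all-gap blocks with a homolog.

    A candidate is emitted when the target species' row is entirely gapped
    over the block, at least one other species has residues there, and at
    least one query peptide survives the 6 aa minimum.
    """
    if aln.X is None:
        raise ValueError("exon blocks X not derived; call derive_exon_blocks first")
    candidates: list[MissingExonCandidate] = []
    for k, sp in enumerate(aln.species):
        for bi, (b, e) in enumerate(aln.X):
            block_cells = aln.C[:, b - 1 : e]
            if (block_cells[k] != GAP).any():
                continue
            others = [i for i in range(aln.n_species) if i != k]
            if not any((block_cells[i] != GAP).any() for i in others):
                continue
            cand = MissingExonCandidate(aln.gene, sp, bi, (b, e))
            cand.queries = build_query_peptides(aln, cand)
            if not cand.queries:
                logger.info(
                    "%s: block %d missing in %s but no query >= %d aa",
                    aln.gene, bi, sp, MIN_QUERY_LENGTH,
                )
                continue
            candidates.append(cand)
    return candidates


def compute_search_window(
    aln: AllExonAlignment,
    candidate: MissingExonCandidate,
    chrom_length: int | None = None,
    pad: int = DEFAULT_WINDOW_PAD,
) -> SearchWindow | None:
    """Bound the genomic interval where the missing exon must reside.

    The window runs from the codon coordinate of the target species' nearest
    residue upstream of the block (in protein order) to the nearest residue
    downstream. A missing flank is replaced by a ``pad`` nt extension from
    the present one; both ends are clamped to the chromosome. On the minus
    strand the flanking coordinates arrive in inverted genomic order and are
    swapped so that L < R always holds on the reference.

    Returns None (logged) when the species has no mapped residue on either
    side — there is nothing to anchor the search.
    """
    k = aln.species_index(candidate.target_species)
    b, e = candidate.block
    q = aln.Q[k]
    up = q[: b - 1]
    down = q[e:]
    up_coord = int(up[up != NO_COORD][-1]) if (up != NO_COORD).any() else None
    down_coord = int(down[down != NO_COORD][0]) if (down != NO_COORD).any() else None
    if up_coord is None and down_coord is None:
        logger.info(
            "%s: %s has no mapped residue flanking block %d; candidate skipped",
            aln.gene, candidate.target_species, candidate.block_index,
        )
        return None

    strand = aln.strand[candidate.target_species]
    if up_coord is not None and down_coord is not None:
        L, R = min(up_coord, down_coord), max(up_coord, down_coord)
    else:
        anchor = up_coord if up_coord is not None else down_coord
        # which genomic side of the anchor the exon lies on depends on strand
        # and on which flank (protein order) is present
        exon_is_right = (up_coord is not None) == (strand == "+")
        if exon_is_right:
            L, R = anchor, anchor + pad
        else:
            L, R = anchor - pad, anchor

    L = max(1, L)
    if chrom_length is not None:
        R = min(R, chrom_length)
    if L >= R:
        logger.info(
            "%s: degenerate window for %s block %d after clamping",
            aln.gene, candidate.target_species, candidate.block_index,
        )
        return None
    return SearchWindow(aln.chrom[candidate.target_species], strand, L, R)
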