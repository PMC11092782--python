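"""Post-processing of accepted exon alignments into final predictions.

Covers four steps: merging predictions of the same exon found through
different query species (keeping the best pairwise identity), classifying
novelty against annotation tracks (existing GTF CDS first, then competing
predictions, else entirely novel), attributing a transitive annotation score
from well-covering homologous source exons, and computing the divergence of a
predicted exon relative to the other exons of its gene for the same species
pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from exhume.collapse import AllExonAlignment
from exhume.formats import GAP, COMPETING_SOURCE, GTF_SOURCE, CdsAnnotation
from exhume.search import ExonAlignment

logger = logging.getLogger("exhume")

OVERLAPS_GTF = "overlaps_gtf"
OVERLAPS_COMPETING = "overlaps_competing"
ENTIRELY_NOVEL = "entirely_novel"

#: a source exon must cover this fraction of the predicted exon's residues
#: for its annotation score to transfer
TRANSITIVE_COVERAGE = 0.85


@dataclass
class SupportingQuery:
    """One query species' accepted alignment backing a prediction."""

    source_species: str
    alignment: ExonAlignment
    pct_identity: float
    source_annotation_score: int | None = None
    block_index: int = 0
    block: tuple[int, int] = (0, 0)


@dataclass
class DivergenceDeltas:
    """Identity of the predicted exon minus reference identities (pct points)."""

    delta_vs_gene_mean: float | None = None
    delta_vs_upstream: float | None = None
    delta_vs_downstream: float | None = None


@dataclass
class ExonPrediction:
    """A located exon in the target species' genome."""

    gene: str
    target_species: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive reference coords
    end: int
    block_index: int
    block: tuple[int, int]
    supports: list[SupportingQuery] = field(default_factory=list)
    novelty: str | None = None
    transitive_score: int | None = None
    deltas: DivergenceDeltas | None = None

    @property
    def best_support(self) -> SupportingQuery:
        return self.supports[0]

    @property
    def pct_identity(self) -> float:
        """Maximum identity over supporting queries (the reported identity)."""
        return self.supports[0].pct_identity

    @property
    def aa_length(self) -> int:
        return (self.end - self.start + 1) // 3


def _sort_supports(supports: list[SupportingQuery]) -> list[SupportingQuery]:
    return sorted(supports, key=lambda s: (-s.pct_identity, s.source_species))


def make_prediction(
    gene: str,
    target_species: str,
    block_index: int,
    block: tuple[int, int],
    support: SupportingQuery,
) -> ExonPrediction:
    a = support.alignment
    support.block_index = block_index
    support.block = block
    return ExonPrediction(
        gene=gene,
        target_species=target_species,
        chrom=a.chrom,
        strand=a.strand,
        start=a.genome_start,
        end=a.genome_end,
        block_index=block_index,
        block=block,
        supports=[support],
    )


def dedup_predictions(preds: list[ExonPrediction]) -> list[ExonPrediction]:
    """Merge predictions (same gene/target species) whose intervals overlap.

    Different query species frequently locate the same exon; overlapping
    intervals (>=1 shared nt, same chromosome) collapse into one record whose
    interval is the union and whose reported alignment is the supporting
    query with the highest percent identity. All supports are retained.
    Idempotent and independent of input order.
    """
    if not preds:
        return []
    ordered = sorted(
        preds,
        key=lambda p: (p.gene, p.target_species, p.chrom, p.start, p.end),
    )
    merged: list[ExonPrediction] = []
    for p in ordered:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.gene == p.gene
            and last.target_species == p.target_species
            and last.chrom == p.chrom
            and p.start <= last.end
        ):
            last.end = max(last.end, p.end)
            last.supports = _sort_supports(last.supports + p.supports)
            best = last.supports[0]
            if best.alignment.strand is not None:
                last.strand = best.alignment.strand
            # interval is the union; block attribution follows the best support
            last.block_index = best.block_index
            last.block = best.block
        else:
            clone = ExonPrediction(
                gene=p.gene,
                target_species=p.target_species,
                chrom=p.chrom,
                strand=p.strand,
                start=p.start,
                end=p.end,
                block_index=p.block_index,
                block=p.block,
                supports=_sort_supports(list(p.supports)),
                novelty=p.novelty,
                transitive_score=p.transitive_score,
                deltas=p.deltas,
            )
            merged.append(clone)
    return merged


def classify_novelty(pred: ExonPrediction, tracks: CdsAnnotation | None) -> str:
    """Label a prediction by what it overlaps (>=1 nt, strand-agnostic).

    Precedence: existing GTF CDS annotation, then competing predictions,
    otherwise entirely novel.
    """
    if tracks is not None:
        if tracks.overlaps(GTF_SOURCE, pred.chrom, pred.start, pred.end):
            pred.novelty = OVERLAPS_GTF
            return pred.novelty
        if tracks.overlaps(COMPETING_SOURCE, pred.chrom, pred.start, pred.end):
            pred.novelty = OVERLAPS_COMPETING
            return pred.novelty
    pred.novelty = ENTIRELY_NOVEL
    return pred.novelty


def _support_coverage_of_prediction(s: SupportingQuery, pred: ExonPrediction) -> float:
    """Fraction of the predicted exon's residues paired with query residues."""
    if pred.aa_length == 0:
        return 0.0
    gap_free = sum(
        1
        for a, b in zip(s.alignment.aligned_query, s.alignment.aligned_target)
        if a != "-" and b != "-"
    )
    return gap_free / pred.aa_length


def transitive_annotation_score(pred: ExonPrediction) -> int | None:
    """Best (lowest) source annotation score among well-covering supports.

    Only supports whose alignment pairs at least 85% of the predicted exon's
    residues qualify; absent if no qualifying support carries a score.
    """
    scores = [
        s.source_annotation_score
        for s in pred.supports
        if s.source_annotation_score is not None
        and _support_coverage_of_prediction(s, pred) >= TRANSITIVE_COVERAGE
    ]
    pred.transitive_score = min(scores) if scores else None
    return pred.transitive_score


def block_pair_identity(
    aln: AllExonAlignment, k1: int, k2: int, block: tuple[int, int]
) -> float | None:
    """Gap-free-column percent identity of two collapsed rows over one block.

    None when the pair shares no gap-free column in the block.
    """
    b, e = block
    r1 = aln.C[k1, b - 1 : e]
    r2 = aln.C[k2, b - 1 : e]
    mask = (r1 != GAP) & (r2 != GAP)
    n = int(mask.sum())
    if n == 0:
        return None
    return 100.0 * int((r1[mask] == r2[mask]).sum()) / n


def divergence_deltas(pred: ExonPrediction, aln: AllExonAlignment) -> DivergenceDeltas:
    """Compare the predicted exon's identity to other exons of the gene.

    For the (target, best query) species pair, the identity of every exon
    block where both rows have residues is computed; the deltas report the
    prediction's identity minus (i) the unweighted mean of those block
    identities, (ii) the nearest upstream block's identity, and (iii) the
    nearest downstream block's identity. Each delta is absent when its
    reference does not exist.
    """
    if aln.X is None:
        raise ValueError("exon blocks X not derived")
    k_target = aln.species_index(pred.target_species)
    k_query = aln.species_index(pred.best_support.source_species)
    per_block: list[tuple[int, float]] = []
    for bi, block in enumerate(aln.X):
        ident = block_pair_identity(aln, k_target, k_query, block)
        if ident is not None:
            per_block.append((bi, ident))
    deltas = DivergenceDeltas()
    if per_block:
        mean = sum(v for _, v in per_block) / len(per_block)
        deltas.delta_vs_gene_mean = pred.pct_identity - mean
        ups = [v for bi, v in per_block if bi < pred.block_index]
        downs = [v for bi, v in per_block if bi > pred.block_index]
        if ups:
            deltas.delta_vs_upstream = pred.pct_identity - ups[-1]
        if downs:
            deltas.delta_vs_downstream = pred.pct_identity - downs[0]
    pred.deltas = deltas
    return deltas
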