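"""End-to-end per-family pipeline: collapse, detect, search, annotate.

`run_family` is the library entry point the CLI wraps: it takes one gene
family's isoform alignment, the per-species genomes, and optional annotation
tracks, and returns the collapsed alignment, the deduplicated and annotated
exon predictions, and per-stage counters. Families are independent units of
work, so a multi-family run may process them concurrently; outputs do not
depend on processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from exhume import annotate, detect, search
from exhume.collapse import AllExonAlignment, collapse_isoforms, derive_exon_blocks
from exhume.detect import DEFAULT_WINDOW_PAD
from exhume.formats import CdsAnnotation, GenomeSequence, IsoformAlignment

logger = logging.getLogger("exhume")


@dataclass
class PipelineConfig:
    """All tunables of a run (defaults are the tool's operating point)."""

    min_coverage: float = 0.90  # accepted alignments must cover >=90% of the query
    min_identity: float = 35.0  # percent, gap-free columns
    window_pad: int = DEFAULT_WINDOW_PAD  # one-sided fallback window size, nt
    max_codon_step: int = 6  # coordinate jump that declares an intron, nt
    seed_min_score: float = search.DEFAULT_SEED_MIN_SCORE
    margin_codons: int = search.DEFAULT_MARGIN_CODONS
    gap_open: float = search.DEFAULT_GAP_OPEN
    gap_extend: float = search.DEFAULT_GAP_EXTEND
    seed_backend: str = "internal"  # internal | tblastn
    threads: int = 1
    seed: int = 0

    def seed_fn(self):
        if self.seed_backend == "internal":
            return search.seed_search
        if self.seed_backend == "tblastn":
            return search.tblastn_seed_search
        raise ValueError(f"unknown seed backend {self.seed_backend!r}")


@dataclass
class FamilyStats:
    candidates: int = 0
    windows_searched: int = 0
    candidates_skipped: int = 0
    alignments_scored: int = 0
    accepted: int = 0
    rejected: dict = field(default_factory=dict)
    predictions: int = 0
    novel: int = 0

    def merge(self, other: "FamilyStats") -> None:
        self.candidates += other.candidates
        self.windows_searched += other.windows_searched
        self.candidates_skipped += other.candidates_skipped
        self.alignments_scored += other.alignments_scored
        self.accepted += other.accepted
        self.predictions += other.predictions
        self.novel += other.novel
        for k, v in other.rejected.items():
            self.rejected[k] = self.rejected.get(k, 0) + v


def run_family(
    aln: IsoformAlignment,
    genomes: Mapping[str, GenomeSequence],
    tracks: Mapping[str, CdsAnnotation] | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[AllExonAlignment, list[annotate.ExonPrediction], FamilyStats]:
    """Process one gene family end to end.

    Steps: collapse isoforms per species, partition into exon blocks, detect
    all-gap blocks with homologs elsewhere, bound the search window from the
    flanking codon coordinates, seed + realign every query peptide, accept
    full-length high-identity alignments, merge same-exon hits, and annotate
    novelty / transitive score / divergence deltas.
    """
    cfg = cfg or PipelineConfig()
    tracks = tracks or {}
    stats = FamilyStats()
    seed_fn = cfg.seed_fn()

    collapsed = collapse_isoforms(aln)
    derive_exon_blocks(collapsed, max_codon_step=cfg.max_codon_step)
    candidates = detect.find_missing_exons(collapsed)
    stats.candidates = len(candidates)

    raw_preds: list[annotate.ExonPrediction] = []
    for cand in candidates:
        genome = genomes.get(cand.target_species)
        if genome is None:
            logger.warning("no genome for %s; candidate skipped", cand.target_species)
            stats.candidates_skipped += 1
            continue
        chrom = collapsed.chrom[cand.target_species]
        window = detect.compute_search_window(
            collapsed, cand, chrom_length=genome.length(chrom), pad=cfg.window_pad
        )
        if window is None:
            stats.candidates_skipped += 1
            continue
        window_dna = genome.fetch(window.chrom, window.L, window.R, window.strand)
        stats.windows_searched += 1
        for query in cand.queries:
            seeds = seed_fn(query.peptide, window_dna, min_score=cfg.seed_min_score)
            for seed in seeds:
                a = search.sw_align(
                    query.peptide,
                    window_dna,
                    seed,
                    window=window,
                    margin_codons=cfg.margin_codons,
                    gap_open=cfg.gap_open,
                    gap_extend=cfg.gap_extend,
                )
                stats.alignments_scored += 1
                verdict = search.accept_prediction(a, cfg)
                if not verdict.accepted:
                    stats.rejected[verdict.reason] = (
                        stats.rejected.get(verdict.reason, 0) + 1
                    )
                    continue
                stats.accepted += 1
                support = annotate.SupportingQuery(
                    source_species=query.source_species,
                    alignment=a,
                    pct_identity=a.pct_identity,
                    source_annotation_score=query.source_annotation_score,
                )
                raw_preds.append(
                    annotate.make_prediction(
                        aln.gene, cand.target_species, cand.block_index, cand.block, support
                    )
                )

    preds = annotate.dedup_predictions(raw_preds)
    for p in preds:
        annotate.classify_novelty(p, tracks.get(p.target_species))
        annotate.transitive_annotation_score(p)
        annotate.divergence_deltas(p, collapsed)
        if p.novelty == annotate.ENTIRELY_NOVEL:
            stats.novel += 1
    stats.predictions = len(preds)
    return collapsed, preds, stats
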