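"""Result writers: per-species BED, the global sorted hit report, per-gene dirs.

Three output surfaces, all deterministic byte-for-byte given identical inputs
and configuration:

* one 6-column BED per target species (0-based half-open, percent identity as
  the penultimate field, name encoding gene family, query species, and exon
  block);
* ``Hits-by-Pct-ID.out``: every prediction, sorted by descending alignment
  percent identity, with genomic region, amino-acid length, and annotation
  overlap;
* ``Results-by-Gene/<gene>/``: plain-text pairwise alignment renderings of
  each predicted exon against its query exons, plus the collapsed C matrix
  (aligned FASTA) and Q matrix (codon-position mapping dialect).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from exhume.annotate import ExonPrediction, OVERLAPS_GTF
from exhume.collapse import AllExonAlignment, write_collapsed

logger = logging.getLogger("exhume")

BED_HEADER = "#chrom\tstart\tend\tname\tpct_identity\tstrand"
HITS_FILENAME = "Hits-by-Pct-ID.out"
GENE_DIRNAME = "Results-by-Gene"


def bed_name(pred: ExonPrediction) -> str:
    return f"{pred.gene}|{pred.best_support.source_species}|e{pred.block_index + 1}"


def write_bed(preds: Sequence[ExonPrediction], species: str, path: str | Path) -> Path:
    """Write one species' predictions as 6-column BED (identity penultimate)."""
    path = Path(path)
    rows = sorted(
        (p for p in preds if p.target_species == species),
        key=lambda p: (p.chrom, p.start, p.end, p.gene),
    )
    lines = [BED_HEADER]
    for p in rows:
        lines.append(
            f"{p.chrom}\t{p.start - 1}\t{p.end}\t{bed_name(p)}\t"
            f"{p.pct_identity:.1f}\t{p.strand}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _hit_sort_key(p: ExonPrediction):
    return (-p.pct_identity, p.gene, p.target_species, p.chrom, p.start, p.end)


def write_hits_report(preds: Sequence[ExonPrediction], path: str | Path) -> Path:
    """All predictions sorted by descending percent identity (ties lexical)."""
    path = Path(path)
    lines = [
        "#rank\tgene\ttarget_species\tregion\taa_length\tpct_identity\t"
        "gtf_overlap\tnovelty"
    ]
    for rank, p in enumerate(sorted(preds, key=_hit_sort_key), start=1):
        region = f"{p.chrom}:{p.start}-{p.end}({p.strand})"
        gtf_flag = "yes" if p.novelty == OVERLAPS_GTF else "no"
        lines.append(
            f"{rank}\t{p.gene}\t{p.target_species}\t{region}\t{p.aa_length}\t"
            f"{p.pct_identity:.1f}\t{gtf_flag}\t{p.novelty}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def render_alignment(pred: ExonPrediction, width: int = 60) -> str:
    """Human-readable rendering of every supporting query alignment."""
    out: list[str] = []
    out.append(
        f"Predicted exon: {pred.target_species} {pred.chrom}:"
        f"{pred.start}-{pred.end}({pred.strand})  gene={pred.gene}  "
        f"block=e{pred.block_index + 1}  aa_length={pred.aa_length}"
    )
    if pred.novelty:
        out.append(f"Novelty: {pred.novelty}")
    if pred.transitive_score is not None:
        out.append(f"Transitive annotation score: {pred.transitive_score}")
    for s in pred.supports:
        a = s.alignment
        out.append("")
        out.append(
            f"Query exon from {s.source_species}  pct_identity={s.pct_identity:.1f}  "
            f"score={a.score:g}  frame={a.frame}"
        )
        out.append(
            f"Target region: {a.chrom}:{a.genome_start}-{a.genome_end}({a.strand})"
        )
        aq, at = a.aligned_query, a.aligned_target
        mid = "".join(
            "|" if x == y and x != "-" else " " for x, y in zip(aq, at)
        )
        for i in range(0, len(aq), width):
            out.append(f"  query  {aq[i : i + width]}")
            out.append(f"         {mid[i : i + width]}")
            out.append(f"  target {at[i : i + width]}")
    return "\n".join(out) + "\n"


def write_gene_results(
    gene: str,
    aln: AllExonAlignment,
    preds: Sequence[ExonPrediction],
    outdir: str | Path,
) -> Path:
    """Per-gene directory: alignment renderings plus persisted C and Q."""
    gene_dir = Path(outdir) / gene
    gene_dir.mkdir(parents=True, exist_ok=True)
    write_collapsed(aln, gene_dir / f"{gene}.collapsed.afa", gene_dir / f"{gene}.collapsed.map")
    for p in sorted(preds, key=lambda p: (p.target_species, p.chrom, p.start)):
        fname = f"exon_{p.target_species}_{p.chrom}_{p.start}_{p.end}.txt"
        (gene_dir / fname).write_text(render_alignment(p))
    return gene_dir
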