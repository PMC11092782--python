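"""Collapse isoform alignments into per-species all-exon rows.

Every isoform of one species covers some subset of the gene's exons. Because a
splice-aware MSA places residues encoded by the same codon in the same column,
the union of all isoform rows of a species collapses into a single row: the
*all-exon representation*. The collapsed matrix ``C`` has one row per species
and the same column count as the input; ``Q`` carries the codon
middle-nucleotide coordinate of every collapsed residue.

The column ranges where coordinates jump by more than a codon (an intron)
partition the alignment into exon blocks ``X`` — the unit at which missing
exons are later detected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from exhume.formats import (
    GAP,
    NO_COORD,
    IsoformAlignment,
    IsoformRecord,
    read_isoform_alignment,
    write_isoform_alignment,
)

logger = logging.getLogger("exhume")

#: coordinate gap between adjacent columns above which an intron is declared;
#: contiguous coding steps by 3 nt, 6 tolerates one skipped codon.
DEFAULT_MAX_CODON_STEP = 6

#: annotation score worse than any real one, used when a row has no score
_NO_SCORE = 6


@dataclass
class AllExonAlignment:
    """Collapsed per-species alignment: matrices C (residues) and Q (coords).

    ``A`` tracks, per cell, the best (lowest) annotation score among the
    isoforms that contributed a residue there (0 = no score available).
    ``X`` is the list of exon-block column ranges, 1-based inclusive, tiling
    the full column range once :func:`derive_exon_blocks` has run.
    """

    gene: str
    species: list[str]
    C: np.ndarray  # (n_species, m) single characters
    Q: np.ndarray  # (n_species, m) int64, 0 where gapped
    A: np.ndarray  # (n_species, m) int8 annotation scores, 0 = absent
    chrom: dict[str, str]
    strand: dict[str, str]
    X: list[tuple[int, int]] | None = None
    conflict_columns: int = 0

    @property
    def n_species(self) -> int:
        return self.C.shape[0]

    @property
    def n_cols(self) -> int:
        return self.C.shape[1]

    def species_index(self, species: str) -> int:
        return self.species.index(species)

    def row_string(self, k: int) -> str:
        return "".join(self.C[k])

    def all_exon_sequence(self, k: int) -> str:
        """E(k): the ungapped union-of-exons residue string of species k."""
        return self.row_string(k).replace(GAP, "")

    def block_residues(self, k: int, block: tuple[int, int]) -> str:
        b, e = block
        return "".join(self.C[k, b - 1 : e])

    def to_isoform_alignment(self) -> IsoformAlignment:
        """View each collapsed row as a single pseudo-isoform (for serialization)."""
        rows = [
            IsoformRecord(sp, sp, self.chrom[sp], self.strand[sp], None)
            for sp in self.species
        ]
        return IsoformAlignment(self.gene, rows, self.C.copy(), self.Q.copy())


def collapse_isoforms(aln: IsoformAlignment) -> AllExonAlignment:
    """Collapse all isoforms of each species into one all-exon row.

    A cell of ``C`` is a residue iff at least one isoform of that species has
    a residue in that column. When isoforms disagree on the (residue,
    coordinate) pair at a column — dual-frame coding — a simple majority-rule
    vote decides; ties go to the isoform with the best (lowest) annotation
    score, then to the earliest row. Conflicting columns are counted.
    """
    roster = aln.species_roster
    m = aln.n_cols
    n = len(roster)
    C = np.full((n, m), GAP, dtype="<U1")
    Q = np.zeros((n, m), dtype=np.int64)
    A = np.zeros((n, m), dtype=np.int8)
    chrom = {}
    strand = {}
    conflicts = 0

    rows_by_species: dict[str, list[int]] = {sp: [] for sp in roster}
    for i, rec in enumerate(aln.rows):
        rows_by_species[rec.species].append(i)

    for k, sp in enumerate(roster):
        idx = rows_by_species[sp]
        chrom[sp] = aln.rows[idx[0]].chrom
        strand[sp] = aln.rows[idx[0]].strand
        sub_M = aln.M[idx]
        sub_P = aln.P[idx]
        occupied = np.flatnonzero((sub_M != GAP).any(axis=0))
        for j in occupied:
            contrib = [
                (sub_M[r, j], int(sub_P[r, j]), idx[r])
                for r in range(len(idx))
                if sub_M[r, j] != GAP
            ]
            values = Counter((aa, pos) for aa, pos, _ in contrib)
            if len(values) > 1:
                conflicts += 1
                top = values.most_common()
                best_count = top[0][1]
                tied = {val for val, cnt in top if cnt == best_count}
                if len(tied) == 1:
                    aa, pos = top[0][0]
                else:
                    # ties: best-evidenced isoform wins, then input order
                    def rank(entry):
                        aa_, pos_, row_i = entry
                        score = aln.rows[row_i].score
                        return (score if score is not None else _NO_SCORE, row_i)

                    aa, pos, _ = min(
                        (c for c in contrib if (c[0], c[1]) in tied), key=rank
                    )
            else:
                aa, pos = next(iter(values))
            C[k, j] = aa
            Q[k, j] = pos
            scores = [
                aln.rows[row_i].score
                for _, _, row_i in contrib
                if aln.rows[row_i].score is not None
            ]
            if scores:
                A[k, j] = min(scores)

    if conflicts:
        logger.info("%s: %d conflicting columns resolved by vote", aln.gene, conflicts)
    return AllExonAlignment(
        gene=aln.gene,
        species=roster,
        C=C,
        Q=Q,
        A=A,
        chrom=chrom,
        strand=strand,
        conflict_columns=conflicts,
    )


def derive_exon_blocks(
    aln: AllExonAlignment, max_codon_step: int = DEFAULT_MAX_CODON_STEP
) -> AllExonAlignment:
    """Partition the alignment columns into exon-block ranges X.

    A block boundary falls between columns j and j+1 whenever any species with
    coordinates at both columns jumps by more than ``max_codon_step``
    nucleotides there. Boundaries from all species are unioned so a single
    tuple list serves the whole family; X always tiles columns 1..m.
    """
    m = aln.n_cols
    boundaries: set[int] = set()
    for k in range(aln.n_species):
        q = aln.Q[k]
        both = (q[:-1] != NO_COORD) & (q[1:] != NO_COORD)
        jump = np.abs(q[1:] - q[:-1]) > max_codon_step
        # boundary after 1-based column j  <=>  index j-1 here
        boundaries.update((np.flatnonzero(both & jump) + 1).tolist())
    cuts = sorted(boundaries)
    X: list[tuple[int, int]] = []
    start = 1
    for c in cuts:
        X.append((start, c))
        start = c + 1
    X.append((start, m))
    aln.X = X
    return aln


# ---------------------------------------------------------------------------
# C/Q serialization (aligned FASTA + mapping dialect)
# ---------------------------------------------------------------------------


def write_collapsed(aln: AllExonAlignment, fasta_path: str | Path, map_path: str | Path) -> None:
    """Persist C as aligned FASTA and Q in the codon-position mapping dialect."""
    write_isoform_alignment(aln.to_isoform_alignment(), fasta_path, map_path)


def read_collapsed(fasta_path: str | Path, map_path: str | Path, gene: str | None = None) -> AllExonAlignment:
    """Inverse of :func:`write_collapsed` (X and A are not persisted)."""
    iso = read_isoform_alignment(fasta_path, map_path, gene=gene)
    collapsed = collapse_isoforms(iso)
    collapsed.gene = gene or iso.gene
    return collapsed
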