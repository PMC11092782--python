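"""Readers and validators for external inputs.

Three kinds of files are consumed:

* genome FASTA, accessed lazily through :class:`FastaGenome` (pyfaidx-backed);
* splice-aware isoform MSAs: an aligned FASTA whose header grammar is
  ``>isoform_id species=<s> chrom=<c> strand=<+|-> [score=<1-5>]``, paired with
  a codon-position mapping file that stores, for every non-gap residue, the
  genomic position of the middle nucleotide of its encoding codon;
* annotation tracks: GTF (CDS features only) and BED files of competing exon
  predictions.

All genomic coordinates are handled internally as 1-based inclusive on the
forward strand of the reference; BED's 0-based half-open convention is
converted at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

logger = logging.getLogger("exhume")

NUCLEOTIDES = frozenset("ACGTN")


class FormatError(ValueError):
    """Base class for input parsing/validation failures."""


class GenomeError(FormatError):
    """Genome FASTA is missing, empty, duplicated, or non-nucleotide."""


class AlignmentError(FormatError):
    """Aligned FASTA violates the isoform-alignment contract."""


class MappingError(FormatError):
    """Codon-position mapping file disagrees with the alignment."""


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


class GenomeSequence:
    """Random-access nucleotide sequence collection (1-based inclusive)."""

    @property
    def chrom_names(self) -> list[str]:
        raise NotImplementedError

    def length(self, chrom: str) -> int:
        raise NotImplementedError

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the nucleotides of ``chrom[start..end]`` (1-based inclusive).

        ``strand='-'`` returns the reverse complement of the same interval.
        """
        if chrom not in self.chrom_names:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= self.length(chrom)):
            raise GenomeError(
                f"interval {start}..{end} out of bounds for {chrom} "
                f"(length {self.length(chrom)})"
            )
        seq = self._raw_fetch(chrom, start, end).upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise GenomeError(
                f"non-nucleotide characters {sorted(bad)} in {chrom}:{start}-{end}"
            )
        if strand == "-":
            seq = reverse_complement(seq)
        elif strand != "+":
            raise GenomeError(f"invalid strand {strand!r}")
        return seq


class DictGenome(GenomeSequence):
    """In-memory genome, used by the simulator and in tests."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start - 1 : end]


class FastaGenome(GenomeSequence):
    """Indexed on-disk genome backed by pyfaidx."""

    def __init__(self, path: str | Path):
        import pyfaidx

        path = Path(path)
        if not path.exists():
            raise GenomeError(f"genome FASTA not found: {path}")
        try:
            self._fasta = pyfaidx.Fasta(str(path))
        except (ValueError, OSError, pyfaidx.FastaIndexingError) as exc:
            # duplicate headers, empty/bad file, unreadable
            raise GenomeError(f"cannot index genome FASTA {path}: {exc}") from exc
        if len(self._fasta.keys()) == 0:
            raise GenomeError(f"genome FASTA {path} contains no records")
        self.path = path

    @property
    def chrom_names(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start - 1 : end])


def read_genome_fasta(path: str | Path) -> FastaGenome:
    """Open an indexed genome FASTA; every record is addressable by header token."""
    return FastaGenome(path)


# ---------------------------------------------------------------------------
# Isoform alignments (residue matrix M + codon-position matrix P)
# ---------------------------------------------------------------------------

GAP = "-"
#: sentinel in coordinate matrices: no residue at this column
NO_COORD = 0

_HEADER_KV = re.compile(r"^(\w+)=(\S+)$")


@dataclass
class IsoformRecord:
    """Per-row metadata of an isoform alignment."""

    isoform_id: str
    species: str
    chrom: str
    strand: str
    score: int | None = None


@dataclass
class IsoformAlignment:
    """An isoform MSA: residue matrix ``M`` and codon-position matrix ``P``.

    ``M[i, j]`` holds an amino-acid letter or ``'-'``; ``P[i, j]`` holds the
    genomic position of the middle nucleotide of the codon encoding that
    residue, or 0 (``NO_COORD``) exactly where ``M`` has a gap.
    """

    gene: str
    rows: list[IsoformRecord]
    M: np.ndarray  # (n_rows, n_cols) of single characters
    P: np.ndarray  # (n_rows, n_cols) int64, 0 where gapped

    @property
    def n_rows(self) -> int:
        return self.M.shape[0]

    @property
    def n_cols(self) -> int:
        return self.M.shape[1]

    def row_string(self, i: int) -> str:
        return "".join(self.M[i])

    def row_sequence(self, i: int) -> str:
        """The ungapped residue string of row *i* (the input isoform sequence)."""
        return self.row_string(i).replace(GAP, "")

    @property
    def species_roster(self) -> list[str]:
        seen: list[str] = []
        for rec in self.rows:
            if rec.species not in seen:
                seen.append(rec.species)
        return seen

    def validate(self) -> None:
        if self.M.shape != self.P.shape:
            raise AlignmentError("M and P differ in shape")
        if len(self.rows) != self.n_rows:
            raise AlignmentError("row metadata count differs from matrix rows")
        gaps = self.M == GAP
        if not np.array_equal(gaps, self.P == NO_COORD):
            raise MappingError("P must be NULL exactly where M is gapped")
        per_species: dict[str, tuple[str, str]] = {}
        for i, rec in enumerate(self.rows):
            if rec.strand not in "+-":
                raise AlignmentError(f"row {rec.isoform_id}: bad strand {rec.strand!r}")
            key = per_species.setdefault(rec.species, (rec.chrom, rec.strand))
            if key != (rec.chrom, rec.strand):
                raise AlignmentError(
                    f"species {rec.species}: rows disagree on chrom/strand"
                )
            coords = self.P[i][~gaps[i]]
            diffs = np.diff(coords)
            if rec.strand == "+" and np.any(diffs <= 0):
                raise MappingError(
                    f"row {rec.isoform_id}: coordinates not strictly increasing"
                )
            if rec.strand == "-" and np.any(diffs >= 0):
                raise MappingError(
                    f"row {rec.isoform_id}: coordinates not strictly decreasing"
                )


def _parse_msa_header(description: str) -> IsoformRecord:
    tokens = description.split()
    if not tokens:
        raise AlignmentError("empty FASTA header")
    iso_id, kv = tokens[0], {}
    for tok in tokens[1:]:
        m = _HEADER_KV.match(tok)
        if m:
            kv[m.group(1)] = m.group(2)
    for required in ("species", "chrom", "strand"):
        if required not in kv:
            raise AlignmentError(f"header of {iso_id!r} lacks {required}=")
    score = int(kv["score"]) if "score" in kv else None
    if score is not None and not 1 <= score <= 5:
        raise AlignmentError(f"{iso_id}: annotation score {score} outside 1-5")
    return IsoformRecord(iso_id, kv["species"], kv["chrom"], kv["strand"], score)


def _read_mapping_file(path: Path) -> dict[str, list[int]]:
    """Mapping dialect: per isoform, a line with its id then a line of
    comma-separated codon middle-nucleotide positions (one per non-gap residue)."""
    blocks: dict[str, list[int]] = {}
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        iso_id = lines[i].lstrip(">")
        if i + 1 >= len(lines):
            raise MappingError(f"{path}: isoform {iso_id!r} has no coordinate line")
        try:
            coords = [int(x) for x in lines[i + 1].split(",") if x != ""]
        except ValueError as exc:
            raise MappingError(f"{path}: bad coordinate line for {iso_id!r}") from exc
        if iso_id in blocks:
            raise MappingError(f"{path}: duplicate isoform {iso_id!r}")
        blocks[iso_id] = coords
        i += 2
    return blocks


def read_isoform_alignment(
    msa_path: str | Path, map_path: str | Path, gene: str | None = None
) -> IsoformAlignment:
    """Load an isoform MSA plus its codon-position mapping and validate both."""
    msa_path, map_path = Path(msa_path), Path(map_path)
    if not msa_path.exists():
        raise AlignmentError(f"MSA file not found: {msa_path}")
    records = list(SeqIO.parse(str(msa_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {msa_path}")
    widths = {len(r.seq) for r in records}
    if len(widths) != 1:
        raise AlignmentError(f"{msa_path}: ragged alignment (widths {sorted(widths)})")
    m = widths.pop()
    if m == 0:
        raise AlignmentError(f"{msa_path}: zero-width alignment")
    rows = [_parse_msa_header(r.description) for r in records]
    ids = [rec.isoform_id for rec in rows]
    if len(set(ids)) != len(ids):
        raise AlignmentError(f"{msa_path}: duplicate isoform ids")

    M = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    coords_by_id = _read_mapping_file(map_path)
    P = np.zeros(M.shape, dtype=np.int64)
    for i, rec in enumerate(rows):
        if rec.isoform_id not in coords_by_id:
            raise MappingError(f"no mapping block for isoform {rec.isoform_id!r}")
        coords = coords_by_id[rec.isoform_id]
        residue_cols = np.flatnonzero(M[i] != GAP)
        if len(coords) != len(residue_cols):
            raise MappingError(
                f"isoform {rec.isoform_id!r}: {len(coords)} coordinates for "
                f"{len(residue_cols)} residues"
            )
        P[i, residue_cols] = coords

    aln = IsoformAlignment(gene or msa_path.stem, rows, M, P)
    aln.validate()
    return aln


def write_isoform_alignment(
    aln: IsoformAlignment, msa_path: str | Path, map_path: str | Path
) -> None:
    """Exact inverse of :func:`read_isoform_alignment`."""
    msa_lines = []
    map_lines = []
    for i, rec in enumerate(aln.rows):
        header = f">{rec.isoform_id} species={rec.species} chrom={rec.chrom} strand={rec.strand}"
        if rec.score is not None:
            header += f" score={rec.score}"
        msa_lines.append(header)
        row = aln.row_string(i)
        for j in range(0, len(row), 60):
            msa_lines.append(row[j : j + 60])
        coords = aln.P[i][aln.M[i] != GAP]
        map_lines.append(rec.isoform_id)
        map_lines.append(",".join(str(int(c)) for c in coords))
    Path(msa_path).write_text("\n".join(msa_lines) + "\n")
    Path(map_path).write_text("\n".join(map_lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

GTF_SOURCE = "gtf"
COMPETING_SOURCE = "competing"


@dataclass
class CdsAnnotation:
    """Interval store of annotated CDS regions for one species.

    Two sources are kept apart: ``gtf`` (existing annotation) and
    ``competing`` (exon predictions from another tool). Coordinates are
    1-based inclusive.
    """

    trees: dict[str, dict[str, IntervalTree]] = field(
        default_factory=lambda: {GTF_SOURCE: {}, COMPETING_SOURCE: {}}
    )

    def add(self, source: str, chrom: str, start: int, end: int) -> None:
        if start > end:
            raise FormatError(f"interval start {start} > end {end}")
        self.trees[source].setdefault(chrom, IntervalTree()).addi(start, end + 1)

    def overlaps(self, source: str, chrom: str, start: int, end: int) -> bool:
        """True iff any ``source`` interval shares >=1 nt with start..end."""
        tree = self.trees[source].get(chrom)
        return bool(tree is not None and tree.overlap(start, end + 1))

    def count(self, source: str) -> int:
        return sum(len(t) for t in self.trees[source].values())


def _parse_gtf_cds(path: Path, store: CdsAnnotation) -> tuple[int, int]:
    kept = malformed = 0
    total = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            total += 1
            parts = line.split("\t")
            if len(parts) < 8:
                malformed += 1
                continue
            if parts[2] != "CDS":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                malformed += 1
                continue
            if start > end:
                malformed += 1
                continue
            store.add(GTF_SOURCE, parts[0], start, end)
            kept += 1
    if total and malformed == total:
        raise FormatError(f"{path}: every line malformed")
    if malformed:
        logger.warning("%s: skipped %d malformed GTF lines", path, malformed)
    if total and kept == 0:
        logger.warning("%s: no CDS features found", path)
    return kept, malformed


def _parse_bed(path: Path, store: CdsAnnotation) -> tuple[int, int]:
    kept = malformed = 0
    total = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            total += 1
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                malformed += 1
                continue
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError:
                malformed += 1
                continue
            if start0 >= end:
                malformed += 1
                continue
            # BED 0-based half-open -> 1-based inclusive
            store.add(COMPETING_SOURCE, parts[0], start0 + 1, end)
            kept += 1
    if total and malformed == total:
        raise FormatError(f"{path}: every line malformed")
    if malformed:
        logger.warning("%s: skipped %d malformed BED lines", path, malformed)
    return kept, malformed


def read_cds_annotations(
    gtf_path: str | Path | None = None,
    bed_paths: Sequence[str | Path] = (),
) -> CdsAnnotation:
    """Build one species' CDS interval store from a GTF and/or BED tracks.

    Only GTF features of type ``CDS`` are used; BED intervals are taken
    verbatim as competing predictions. Malformed lines are logged and skipped;
    a file with no well-formed line at all raises.
    """
    store = CdsAnnotation()
    if gtf_path is not None:
        _parse_gtf_cds(Path(gtf_path), store)
    for bed in bed_paths:
        _parse_bed(Path(bed), store)
    return store
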