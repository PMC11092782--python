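"""Synthetic multi-species gene families with planted hidden exons.

The generator emulates the evolutionary scenario the tool targets: a
multi-exon gene shared by several species, where one species' sampled
isoforms happen not to include a particular exon even though a homolog of it
sits, intact, in that species' genome between the neighboring exons. Every
family comes with its ground truth (the planted interval and peptide), so
recovery can be measured exactly.

Model: an ancestral protein of ``n_exons`` exons is drawn; species 1 carries
it verbatim and each further species carries a copy of every exon mutated by
substitutions to a target percent identity. Exon peptides are back-translated
with uniformly random synonymous codons and laid on a toy chromosome with
random GT..AG introns and flanking sequence. A hidden exon is present in the
target species' genome — mutated to the planted identity relative to the
first *other* species' copy — but omitted from all of that species' isoforms.
Everything is a pure function of the spec (seed included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from exhume.formats import (
    DictGenome,
    IsoformAlignment,
    IsoformRecord,
    CdsAnnotation,
    GTF_SOURCE,
    write_isoform_alignment,
)

logger = logging.getLogger("exhume")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_table.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class HiddenExon:
    """An exon to omit from one species' isoforms (but plant in its genome)."""

    species_index: int
    exon_index: int
    identity: float = 60.0  # planted aa identity vs the first other species' copy


@dataclass(frozen=True)
class SyntheticFamilySpec:
    seed: int = 0
    gene: str = "FAM0"
    n_species: int = 3
    n_exons: int = 4
    exon_len_range: tuple[int, int] = (20, 60)  # aa; typical internal exon
    intron_len_range: tuple[int, int] = (100, 2000)  # nt
    pairwise_identity: float = 85.0  # percent aa identity between species pairs
    hidden_exons: tuple[HiddenExon, ...] = ()
    strands: tuple[str, ...] | None = None  # per species; default all '+'
    flank_policy: str = "both"  # both | no-upstream | no-downstream
    isoforms_per_species: int = 2


@dataclass
class TruthExon:
    target_species: str
    exon_index: int
    chrom: str
    strand: str
    start: int  # 1-based inclusive reference coords of the planted exon
    end: int
    peptide: str
    planted_identity: float


@dataclass
class TruthSet:
    exons: list[TruthExon] = field(default_factory=list)


@dataclass
class SyntheticFamily:
    spec: SyntheticFamilySpec
    genomes: dict[str, DictGenome]
    alignment: IsoformAlignment
    truth: TruthSet
    cds: dict[str, list[tuple[str, int, int, str]]]  # annotated (non-hidden) exons

    def annotation_tracks(self) -> dict[str, CdsAnnotation]:
        tracks: dict[str, CdsAnnotation] = {}
        for sp, intervals in self.cds.items():
            store = CdsAnnotation()
            for chrom, start, end, _strand in intervals:
                store.add(GTF_SOURCE, chrom, start, end)
            tracks[sp] = store
        return tracks


def plant_divergence(peptide: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues so gap-free identity to the input hits the target.

    The substitution count is the rounded exact value, so the achieved
    identity is within one residue's granularity of the request. No indels.
    """
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    n = len(peptide)
    n_sub = int(round(n * (1.0 - identity / 100.0)))
    if n_sub == 0:
        return peptide
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(peptide)
    for pos in sorted(int(p) for p in positions):
        alternatives = AMINO_ACIDS.replace(out[pos], "")
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _random_peptide(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _back_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS_BY_AA[aa][int(rng.integers(len(CODONS_BY_AA[aa])))] for aa in peptide
    )


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def _random_intron(length: int, rng: np.random.Generator) -> str:
    return "GT" + _random_dna(length - 4, rng) + "AG"


def generate_family(spec: SyntheticFamilySpec) -> SyntheticFamily:
    """Build genomes, the isoform alignment, and the truth set for one family."""
    rng = np.random.default_rng(spec.seed)
    n_sp = spec.n_species
    if n_sp < 2:
        raise ValueError("need at least 2 species")
    species = [f"sp{i + 1}" for i in range(n_sp)]
    strands = spec.strands or ("+",) * n_sp
    if len(strands) != n_sp:
        raise ValueError("strands must list one strand per species")
    hidden_by_species: dict[int, dict[int, HiddenExon]] = {}
    for h in spec.hidden_exons:
        if not 0 <= h.exon_index < spec.n_exons:
            raise ValueError(f"hidden exon index {h.exon_index} out of range")
        if not 0 <= h.species_index < n_sp:
            raise ValueError(f"hidden species index {h.species_index} out of range")
        hidden_by_species.setdefault(h.species_index, {})[h.exon_index] = h

    lo, hi = spec.exon_len_range
    if lo < 2:
        raise ValueError("exons must be at least 2 aa")
    exon_lens = [int(x) for x in rng.integers(lo, hi + 1, size=spec.n_exons)]
    ancestor = [_random_peptide(n, rng) for n in exon_lens]

    # per-species exon peptides: species 1 = ancestor, others mutated
    peptides: list[list[str]] = []
    for si in range(n_sp):
        if si == 0:
            peptides.append(list(ancestor))
        else:
            peptides.append(
                [plant_divergence(p, spec.pairwise_identity, rng) for p in ancestor]
            )

    genomes: dict[str, DictGenome] = {}
    truth = TruthSet()
    cds: dict[str, list[tuple[str, int, int, str]]] = {}
    # codon middle coordinate of residue r of exon x, per species (layout coords)
    middles: list[list[list[int]]] = []
    chrom_lens: list[int] = []

    for si, sp in enumerate(species):
        hidden_here = hidden_by_species.get(si, {})
        genome_peps = list(peptides[si])
        for xi, h in hidden_here.items():
            source_si = next(j for j in range(n_sp) if j != si)
            genome_peps[xi] = plant_divergence(peptides[source_si][xi], h.identity, rng)

        flank5 = _random_dna(int(rng.integers(300, 801)), rng)
        flank3 = _random_dna(int(rng.integers(300, 801)), rng)
        parts = [flank5]
        pos = len(flank5) + 1  # next free 1-based layout position
        sp_middles: list[list[int]] = []
        exon_spans: list[tuple[int, int]] = []
        for xi, pep in enumerate(genome_peps):
            if xi > 0:
                ilen = int(rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1))
                parts.append(_random_intron(ilen, rng))
                pos += ilen
            coding = _back_translate(pep, rng)
            parts.append(coding)
            sp_middles.append([pos + 3 * r + 1 for r in range(len(pep))])
            exon_spans.append((pos, pos + len(coding) - 1))
            pos += len(coding)
        parts.append(flank3)
        layout = "".join(parts)
        N = len(layout)
        chrom = f"{spec.gene}_chr1"

        if strands[si] == "-":
            seq = _revcomp(layout)
            sp_middles = [[N - p + 1 for p in ex] for ex in sp_middles]
            exon_spans = [(N - e + 1, N - s + 1) for s, e in exon_spans]
        else:
            seq = layout
        genomes[sp] = DictGenome({chrom: seq})
        middles.append(sp_middles)
        chrom_lens.append(N)

        cds[sp] = [
            (chrom, s, e, strands[si])
            for xi, (s, e) in enumerate(exon_spans)
            if xi not in hidden_here
        ]
        for xi, h in hidden_here.items():
            s, e = exon_spans[xi]
            truth.exons.append(
                TruthExon(
                    target_species=sp,
                    exon_index=xi,
                    chrom=chrom,
                    strand=strands[si],
                    start=s,
                    end=e,
                    peptide=genome_peps[xi],
                    planted_identity=h.identity,
                )
            )

    alignment = _build_alignment(
        spec, species, strands, exon_lens, peptides, middles, hidden_by_species, rng
    )
    return SyntheticFamily(spec, genomes, alignment, truth, cds)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _build_alignment(
    spec: SyntheticFamilySpec,
    species: list[str],
    strands: tuple[str, ...],
    exon_lens: list[int],
    peptides: list[list[str]],
    middles: list[list[list[int]]],
    hidden_by_species: dict[int, dict[int, HiddenExon]],
    rng: np.random.Generator,
) -> IsoformAlignment:
    m = sum(exon_lens)
    offsets = np.cumsum([0] + exon_lens[:-1])
    rows: list[IsoformRecord] = []
    M_rows: list[list[str]] = []
    P_rows: list[list[int]] = []

    for si, sp in enumerate(species):
        hidden_here = set(hidden_by_species.get(si, {}))
        if spec.flank_policy == "no-upstream" and hidden_here:
            hidden_here |= set(range(min(hidden_here)))
        elif spec.flank_policy == "no-downstream" and hidden_here:
            hidden_here |= set(range(max(hidden_here) + 1, spec.n_exons))
        present = [x for x in range(spec.n_exons) if x not in hidden_here]
        iso_exon_sets = [present]
        if spec.isoforms_per_species > 1 and len(present) >= 3:
            drop = present[1 + int(rng.integers(len(present) - 2))]
            iso_exon_sets.append([x for x in present if x != drop])
        for ii, exon_set in enumerate(iso_exon_sets):
            row = ["-"] * m
            pmap = [0] * m
            for xi in exon_set:
                off = int(offsets[xi])
                for r, aa in enumerate(peptides[si][xi]):
                    row[off + r] = aa
                    pmap[off + r] = middles[si][xi][r]
            rows.append(
                IsoformRecord(
                    isoform_id=f"{spec.gene}_{sp}_iso{ii + 1}",
                    species=sp,
                    chrom=f"{spec.gene}_chr1",
                    strand=strands[si],
                    score=1 if ii == 0 else 3,
                )
            )
            M_rows.append(row)
            P_rows.append(pmap)

    aln = IsoformAlignment(
        spec.gene,
        rows,
        np.array(M_rows, dtype="<U1"),
        np.array(P_rows, dtype=np.int64),
    )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# On-disk fixture sets
# ---------------------------------------------------------------------------


def write_fixture_set(families: list[SyntheticFamily], outdir: str | Path) -> None:
    """Write a ready-to-run input set for a collection of families.

    Because each family lives on its own uniquely-named toy chromosome, all
    families of one species share a single genome FASTA and GTF. Produces
    ``genomes/<sp>.fa``, ``gtf/<sp>.gtf``, ``msa/<gene>.afa``,
    ``maps/<gene>.map``, the ``genomes.tsv``/``gtf.tsv`` species->path
    manifests, and ``truth.tsv``.
    """
    outdir = Path(outdir)
    for sub in ("genomes", "msa", "maps", "gtf"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    species = sorted({sp for fam in families for sp in fam.genomes})
    for sp in species:
        with open(outdir / "genomes" / f"{sp}.fa", "w") as fh:
            for fam in families:
                genome = fam.genomes.get(sp)
                if genome is None:
                    continue
                for chrom in genome.chrom_names:
                    fh.write(f">{chrom}\n")
                    seq = genome.fetch(chrom, 1, genome.length(chrom))
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
        with open(outdir / "gtf" / f"{sp}.gtf", "w") as fh:
            for fam in families:
                for chrom, start, end, strand in fam.cds.get(sp, []):
                    fh.write(
                        f"{chrom}\texhume_sim\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                        f'gene_id "{fam.spec.gene}";\n'
                    )
    for fam in families:
        write_isoform_alignment(
            fam.alignment,
            outdir / "msa" / f"{fam.spec.gene}.afa",
            outdir / "maps" / f"{fam.spec.gene}.map",
        )
    # manifests use paths relative to their own location so a fixture set is
    # relocatable and byte-reproducible
    with open(outdir / "genomes.tsv", "w") as fh:
        for sp in species:
            fh.write(f"{sp}\tgenomes/{sp}.fa\n")
    with open(outdir / "gtf.tsv", "w") as fh:
        for sp in species:
            fh.write(f"{sp}\tgtf/{sp}.gtf\n")
    write_truth(families, outdir / "truth.tsv")


def write_truth(families: list[SyntheticFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tspecies\texon_index\tchrom\tstrand\tstart\tend\tidentity\tpeptide\n")
        for fam in families:
            for t in fam.truth.exons:
                fh.write(
                    f"{fam.spec.gene}\t{t.target_species}\t{t.exon_index}\t{t.chrom}\t"
                    f"{t.strand}\t{t.start}\t{t.end}\t{t.planted_identity:g}\t{t.peptide}\n"
                )


def default_recovery_spec(seed: int, planted_identity: float, gene: str = "FAM") -> SyntheticFamilySpec:
    """The standard recovery-experiment condition: one interior hidden exon."""
    return SyntheticFamilySpec(
        seed=seed,
        gene=gene,
        hidden_exons=(HiddenExon(species_index=1, exon_index=1, identity=planted_identity),),
    )
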