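# exhume

**Comparative discovery of unannotated exons from splice-aware protein
isoform alignments.**

The protein isoforms documented for a gene differ between species largely
because different tissues, conditions, and sequencing efforts have been
sampled in each organism — not because the underlying exons are absent. When
an exon is observed in the isoforms of species *T* but in none of the
isoforms of species *S*, its homolog frequently still sits, intact and
unannotated, in the genome of *S* between the neighboring exons. `exhume`
finds such exons systematically. It is aimed at genome annotators and
alternative-splicing researchers who have per-gene, splice-aware isoform
MSAs (plus the protein-to-genome codon coordinates behind them) and want to
turn cross-species isoform diversity into concrete, coordinate-level exon
predictions.

## Method

For each gene family `g` with species roster `S = (s_1 … s_n)`:

1. **Collapse.** The isoform MSA `M_g` (rows = isoforms, with a mapping
   matrix `P_g` giving the genomic position of each residue's codon middle
   nucleotide) is collapsed to one *all-exon* row per species: `C_g(k)` holds
   a residue wherever any isoform of `s_k` has one, and the coordinate matrix
   `Q_g` carries its codon position. Conflicting residue/coordinate pairs at
   a column (dual-frame coding) are resolved by majority vote.
2. **Exon blocks.** Columns are partitioned into blocks `X` by placing a
   boundary wherever any species' coordinates jump by more than one codon
   (default > 6 nt) between adjacent columns — i.e. at introns.
3. **Detect.** A block `(b..e)` whose columns are all gaps in `C_g(k)` while
   another species has residues there is a *missing exon candidate* for
   `s_k`. Each other species' block residues (gaps stripped, minimum 6 aa)
   become a query peptide `O`.
4. **Search.** The candidate must lie between the flanking coordinates
   `L = Q_g(k, b−1)` and `R = Q_g(k, e+1)`; a missing flank is replaced by a
   25,000 nt one-sided extension. The window is translated in all three
   frames; ungapped BLOSUM62 diagonal seeds above threshold are realigned
   with an affine-gap Smith–Waterman (BLOSUM62, gap open 11, extend 1) and
   the local core is extended to the query termini. A prediction is accepted
   if it covers ≥ 90 % of the query at ≥ 35 % identity, where identity is
   the fraction of *gap-free* alignment columns with identical residues.
5. **Annotate & report.** Same-exon hits from different query species are
   merged (best identity reported); each prediction is labelled
   `overlaps_gtf`, `overlaps_competing`, or `entirely_novel` against the
   loaded tracks; a *transitive annotation score* (best UniProt-style score
   1–5 among source exons covering ≥ 85 % of the prediction) and
   divergence deltas versus the gene's other exons are attached.

## Worked example

No downloads are needed: the bundled simulator builds multi-species gene
families with a hidden exon planted in one species' genome (here at 70 %
amino-acid identity to its homolog) and records the ground truth.

```bash
exhume simulate --out demo/input --families 3 --seed 42 --hidden-identity 70
exhume run --msa-dir demo/input/msa --map-dir demo/input/maps \
           --genomes demo/input/genomes.tsv --gtf demo/input/gtf.tsv \
           --out demo/results
```

The run log ends with

```
INFO exhume: families=3 candidates=3 windows=3 accepted=6 predictions=3 novel=3 rejected={} failed=0
```

and `demo/results/sp2.bed` contains one line per discovered exon
(0-based BED; the penultimate field is the alignment percent identity):

```
#chrom	start	end	name	pct_identity	strand
FAM0000_chr1	1522	1675	FAM0000|sp1|e2	70.6	+
FAM0001_chr1	1634	1772	FAM0001|sp1|e2	69.6	+
FAM0002_chr1	1332	1407	FAM0002|sp1|e2	68.0	+
```

Each interval matches the planted truth in `demo/input/truth.tsv` exactly
(e.g. family `FAM0000` planted `FAM0000_chr1:1523-1675`), the name field
records which query species and exon block supported the call, and the
identities sit at the planted 70 % level. `demo/results/Hits-by-Pct-ID.out`
lists the same predictions sorted by identity with their amino-acid lengths
and novelty labels (`entirely_novel` here — the planted exons are excluded
from the simulated GTF), and `demo/results/Results-by-Gene/FAM0000/`
holds the rendered query-vs-prediction alignments plus the collapsed `C`/`Q`
matrices.

## Layout

| module | role |
| --- | --- |
| `exhume.formats` | genome FASTA, isoform MSA + codon-position mapping dialect, GTF/BED tracks |
| `exhume.collapse` | all-exon collapse (`C`, `Q`) and exon-block derivation (`X`) |
| `exhume.detect` | missing-block detection, query peptides, search-window arithmetic |
| `exhume.search` | translated seeding, affine-gap Smith–Waterman, identity, acceptance |
| `exhume.annotate` | same-exon dedup, novelty labels, transitive scores, divergence deltas |
| `exhume.report` | per-species BED, `Hits-by-Pct-ID.out`, `Results-by-Gene/` |
| `exhume.simulate` | synthetic families with planted hidden exons + ground truth |
| `exhume.cli` | `exhume run / simulate / report` |
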