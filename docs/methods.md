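# Methods

This note records the model behind `exhume`, the parameters that matter, the
numerical choices made where the procedure was genuinely open, what the
synthetic data generator does and does not emulate, and known limitations.

## Input model

The unit of work is a gene family: an amino-acid MSA `M_g` of all known
isoforms across species, built splice-aware so that residues encoded by the
same codon share a column, together with a mapping matrix `P_g` holding, for
every non-gap residue, the genomic position of the middle nucleotide of its
codon (NULL at gaps). The MSA dialect read here is aligned FASTA with
`species= chrom= strand= [score=]` header tokens plus a mapping file with one
comma-separated coordinate line per isoform. Validation enforces: equal row
widths, one coordinate per residue, strict monotonicity of coordinates along
a row (increasing on `+`, decreasing on `−`), and a single chrom/strand per
species. Split codons (a codon interrupted by an intron) are represented
only by their middle-nucleotide position; the dialect does not record the
phase, and no attempt is made to resolve it.

All internal coordinates are 1-based inclusive on the forward strand of the
reference; BED's 0-based half-open convention is converted exactly at the
I/O boundary.

## Collapse and exon blocks

Collapsing takes the union of residues across a species' isoforms per
column. Disagreements (possible when a region codes in more than one frame
in different isoforms) are resolved by a majority vote over (residue,
coordinate) pairs. Votes can tie; the tie-break is (1) the value contributed
by the isoform with the best (lowest) annotation score, treating "no score"
as worst, then (2) earliest input row. This is deterministic and favors
better-evidenced sequences. Conflicting columns are counted and logged;
collapse never fails.

Exon block boundaries are placed between adjacent columns where any species'
coordinates jump by more than `max_codon_step` (default 6 nt — contiguous
coding steps by exactly 3 nt, 6 tolerates one skipped codon while any real
intron is orders of magnitude larger). Boundaries are unioned across
species, giving a single block list `X` per family; when species disagree
about a boundary's exact column because of alignment slack, the union keeps
both cuts. `X` always tiles the columns, so every column belongs to exactly
one block.

## Candidate detection and the search window

A candidate is a (species `k`, block `b..e`) pair where row `k` is entirely
gapped over the block and at least one other species is not. Query peptides
are the other species' block residues with gaps stripped; queries below 6 aa
are discarded (too short to seed a reliable translated match), and a
candidate without any surviving query is dropped with a log entry.
Consecutive all-gap blocks are searched independently, one window each.

The window is bounded by the codon coordinates of the target species'
nearest mapped residues upstream and downstream of the block in protein
order (these are columns `b−1` / `e+1` whenever those columns are mapped;
the scan continues past adjacent unmapped columns so that a neighbor block
that is itself missing does not orphan the candidate). A missing flank is
replaced by a one-sided extension of `window_pad` nt (default 25,000 — a
generous bound on mammalian intron+exon spans at this scale). On the minus
strand the two flank coordinates arrive in inverted genomic order and are
swapped, so `L < R` always holds on the reference; endpoints are used
inclusively (the one-codon overlap with flanking exons is harmless to local
alignment) and clamped to `[1, chrom length]`.

## Translated search and alignment

The window sequence is extracted strand-oriented (reverse complement for
`−`) and translated in its three forward frames. Seeding computes the full
BLOSUM62 score matrix of query versus each frame translation and extracts,
per diagonal, every maximal positive-scoring run; runs scoring at least the
seed threshold are kept, and the highest-scoring mutually non-overlapping
hits (on window nucleotides) are returned in deterministic order. The seed
threshold defaults to a raw score of 40 (chosen so that random 25 kb windows
yield an expected false-seed count well below one under Karlin–Altschul
statistics), capped at 80 % of the query's self-score so that minimum-length
6 aa queries remain discoverable. An external `tblastn -subject` backend
implements the identical contract for users who prefer BLAST seeding; the
internal backend is the default because its scores are exactly reproducible
across environments.

Each seed is widened by `margin_codons` (default 15) codons per side,
translated in the seed frame, and realigned to the query with an affine-gap
Smith–Waterman: BLOSUM62, gap of length L costs 11 + L (tblastn's default
scheme; the stop character `*` is scored by the matrix, so a frame-breaking
stop simply scores very poorly). The implementation is the standard
three-state dynamic program with traceback; its optimality is checked in the
test suite against both an exhaustive enumeration of local alignments (tiny
instances) and an independent affine-gap local aligner (random instances).

**Full-exon anchoring.** A maximal-score local alignment sheds terminally
mismatched residues, yet the object being predicted is an exon whose extent
is bounded by the block, so the reported alignment is the optimal local core
extended *ungapped* to the query termini as far as the translated region
allows. Percent identity (fraction of gap-free columns with identical
residues; gap columns excluded from numerator and denominator) and query
coverage are measured on this full-exon alignment, which makes the reported
identity an unbiased estimate of the exon's divergence; the recorded `score`
remains the optimal Smith–Waterman local score. Alignments with no gap-free
column report identity 0 with an explicit flag.

Acceptance requires score > 0, query coverage ≥ `min_coverage` (default
0.90) and identity ≥ `min_identity` (default 35 %). These two thresholds
operationalize "a high-scoring full-length match"; both are configurable
and every rejection is counted by reason. Frameshifts within one exon are
not modeled — each alignment lives in a single frame.

## Merging, novelty, transitive scores, divergence deltas

Predictions for one (gene, target species) whose genomic intervals share at
least one nucleotide are merged: the interval becomes the union and the
reported alignment/identity is the best-identity support; all supports are
retained. Merging is idempotent and independent of input order.

Novelty is assigned by overlap (≥ 1 nt, same chromosome, strand-agnostic —
the conservative choice for calling something "novel") with precedence
existing GTF CDS > competing-prediction track > `entirely_novel`.

The transitive annotation score is the best (minimum, 1–5) source-exon
annotation score among supports whose alignment pairs at least 85 % of the
predicted exon's residues (predicted residue count = interval length / 3);
absent when no qualifying support carries a score. Source scores propagate
from isoform metadata through collapse as the per-column minimum over
contributing isoforms.

Divergence deltas compare the prediction's identity with the other exons of
its gene for the same (target, best-query) species pair: per-block identity
uses the same gap-free-column definition, computed on the collapsed rows
restricted to each block where both species have residues; the gene mean is
the unweighted mean over those blocks (no length weighting — each exon is
one evolutionary unit), and upstream/downstream deltas use the nearest
block with a defined identity. Any delta whose reference does not exist is
reported absent rather than zero.

## Synthetic data generator

The generator emulates the core evolutionary scenario: a multi-exon gene
conserved across species where one species' sampled isoforms miss an exon
that is nonetheless intact in its genome. Defaults: 3 species, 4 exons of
20–60 aa (the typical 120–180 nt internal-exon range), introns of
100–2,000 nt with canonical GT..AG ends, 300–800 nt flanks, and 85 %
pairwise amino-acid identity between species (the typical ortholog identity
among well-studied mammals), implemented by substituting a rounded-exact
number of residues of the ancestral sequence uniformly at random (no rate
matrix — only the identity level matters for recovery experiments, and flat
substitution is the *harder* condition because it yields no conservative,
positively-scoring mismatches; no indels by default). The hidden exon is
mutated to its planted identity relative to the first non-target species'
copy, so a 100 % planting must produce a predicted identity of exactly
100.0. Each species gets two isoforms (the second drops one interior exon)
so collapse is genuinely exercised; annotation (GTF) covers exactly the
non-hidden exons, making a recovered planted exon `entirely_novel` by
construction. Everything is a pure function of the spec, seed included, and
fixture sets are byte-reproducible and relocatable.

What the generator does **not** emulate: alignment errors from a real MSA
pipeline, insertions/deletions between orthologous exons, paralogs,
pseudo-exons, splice-site degeneration, non-uniform codon usage, and
repeat-dense intergenic sequence. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under clean homology at a given
identity level, not that real-genome precision/recall will match.

Experiment sizes were chosen to characterize each property while keeping a
desk-scale run: 50 families per recovery operating point, 150–200 families
for delta centering (two species there, so the "most similar query" involves
no maximum-selection bias and uniform mutation genuinely centers the deltas
near zero), 200 random instances for alignment-optimality checks.

## Determinism and failure isolation

The pipeline contains no randomness; seeds only drive the simulator. All
outputs are pure functions of inputs + configuration: collections are
processed in sorted order, ties broken lexically, and per-family outputs are
written independently, so runs with different thread counts are
byte-identical. In multi-family runs each family is isolated — a malformed
family is logged and skipped without aborting the run, which matters at the
tens-of-thousands-of-families scale the method targets.

## Known limitations

- One frame per alignment: an exon homolog containing a frameshift is found
  only partially (or rejected).
- Windows assume the missing exon lies between its neighbors on the same
  chromosome and strand; trans-splicing and rearrangements are out of scope.
- The window fallback (25 kb) truncates genuinely distant terminal exons.
- Split-codon phase is unresolved by the mapping dialect (middle-nucleotide
  positions only), so predicted intervals can be offset by up to one codon
  at splice boundaries relative to the true exon ends.
- No E-value statistics: seed and acceptance thresholds are score- and
  identity-based; on very large windows, marginal hits near the thresholds
  deserve manual review via the rendered alignments.
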