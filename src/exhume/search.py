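"""Translated search for a missing exon inside its genomic window.

The window DNA (already strand-oriented) is translated in the three forward
frames. Seeding finds, per frame, all maximal positive-scoring ungapped
diagonal runs of the query against the translation (BLOSUM62 units) above a
threshold, and keeps the highest-scoring mutually non-overlapping ones. Each
seed is extended by a fixed codon margin and realigned to the query with an
affine-gap Smith-Waterman. Because an exon homolog should span the whole
query exon, the optimal local core is then extended ungapped to the query
termini within the translated region; percent identity (gap-free columns)
and query coverage are measured on that full-exon alignment, and a
prediction is accepted if it is a (nearly) full-length, sufficiently
identical match.

An external ``tblastn`` backend implements the same seeding contract via
subprocess for users who prefer BLAST statistics; the internal backend is the
default and is exactly deterministic.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from exhume.detect import SearchWindow

logger = logging.getLogger("exhume")

# --- scoring scheme: BLOSUM62, affine gaps, gap of length L costs open + L*extend
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_SEED_MIN_SCORE = 40.0
#: seed threshold is capped at this fraction of the query's ungapped self-score
#: so that minimum-length queries remain findable
SEED_SELF_CAP = 0.8
#: codons added on each side of a seed before Smith-Waterman realignment
DEFAULT_MARGIN_CODONS = 15

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_B62.alphabet)
_CHAR_INDEX = np.full(128, _ALPHABET.index("X"), dtype=np.int64)
for _i, _c in enumerate(_ALPHABET):
    _CHAR_INDEX[ord(_c)] = _i
_MATRIX = np.asarray(_B62, dtype=np.float64)


def _aa_indices(seq: str) -> np.ndarray:
    return _CHAR_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def substitution_score(a: str, b: str) -> float:
    """BLOSUM62 score of a residue pair (unknowns treated as X)."""
    return float(_MATRIX[_CHAR_INDEX[ord(a)], _CHAR_INDEX[ord(b)]])


def self_score(peptide: str) -> float:
    idx = _aa_indices(peptide)
    return float(_MATRIX[idx, idx].sum())


def translate_frame(dna: str, frame: int) -> str:
    """Translate one forward frame; trailing partial codon dropped, stops kept as '*'."""
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


@dataclass
class SeedHit:
    """An ungapped translated hit: window-relative nt interval (1-based incl.)."""

    start: int
    end: int
    frame: int
    score: float


@dataclass
class ExonAlignment:
    """A realigned query-vs-translated-genome local alignment."""

    query_peptide: str
    target_peptide: str  # translated region handed to Smith-Waterman
    aligned_query: str
    aligned_target: str
    frame: int
    score: float
    window_start: int  # nt interval of the aligned target, window-relative
    window_end: int
    chrom: str | None = None
    genome_start: int | None = None  # reference coords, 1-based inclusive
    genome_end: int | None = None
    strand: str | None = None
    pct_identity: float = 0.0
    identity_defined: bool = True
    query_coverage: float = 0.0

    @property
    def target_residues(self) -> int:
        return (self.window_end - self.window_start + 1) // 3


@dataclass
class Acceptance:
    accepted: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def _diagonal_segments(S: np.ndarray, threshold: float):
    """All maximal positive-scoring runs on every diagonal of score matrix S.

    Yields (qs, qe, ts, te, score) with 0-based inclusive residue indices.
    One segment per positive stretch: the best-scoring prefix-maximal run.
    """
    nq, nt = S.shape
    for d in range(-(nq - 1), nt):
        qs0 = max(0, -d)
        ts0 = qs0 + d
        length = min(nq - qs0, nt - ts0)
        diag = S[qs0 + np.arange(length), ts0 + np.arange(length)]
        cur = 0.0
        cur_start = 0
        best = 0.0
        best_span = None
        for i, v in enumerate(diag):
            cur += v
            if cur > best:
                best = cur
                best_span = (cur_start, i)
            if cur < 0:
                if best >= threshold and best_span is not None:
                    yield (
                        qs0 + best_span[0], qs0 + best_span[1],
                        ts0 + best_span[0], ts0 + best_span[1],
                        best,
                    )
                cur = 0.0
                cur_start = i + 1
                best = 0.0
                best_span = None
        if best >= threshold and best_span is not None:
            yield (
                qs0 + best_span[0], qs0 + best_span[1],
                ts0 + best_span[0], ts0 + best_span[1],
                best,
            )


def seed_search(
    peptide: str,
    window_dna: str,
    min_score: float = DEFAULT_SEED_MIN_SCORE,
) -> list[SeedHit]:
    """Translated ungapped search of the query against all 3 forward frames.

    Returns the highest-scoring mutually non-overlapping (on the window) hits
    above the seed threshold, sorted by descending score. Deterministic.
    """
    if len(window_dna) < 3 * len(peptide) and len(window_dna) < 18:
        logger.info("window of %d nt too short to seed", len(window_dna))
        return []
    threshold = min(min_score, SEED_SELF_CAP * self_score(peptide))
    q_idx = _aa_indices(peptide)
    raw: list[SeedHit] = []
    for frame in range(3):
        prot = translate_frame(window_dna, frame)
        if not prot:
            continue
        t_idx = _aa_indices(prot)
        S = _MATRIX[q_idx[:, None], t_idx[None, :]]
        for qs, qe, ts, te, score in _diagonal_segments(S, threshold):
            raw.append(
                SeedHit(
                    start=frame + 3 * ts + 1,
                    end=frame + 3 * te + 3,
                    frame=frame,
                    score=float(score),
                )
            )
    # greedy selection of non-overlapping hits, best first; deterministic ties
    raw.sort(key=lambda h: (-h.score, h.start, h.frame))
    chosen: list[SeedHit] = []
    for hit in raw:
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: (-h.score, h.start))
    return chosen


def tblastn_seed_search(
    peptide: str,
    window_dna: str,
    min_score: float = DEFAULT_SEED_MIN_SCORE,
    tblastn_exe: str = "tblastn",
) -> list[SeedHit]:
    """Seed via an external ``tblastn -subject`` call (same contract).

    Only plus-strand subject hits are used (the window is already
    strand-oriented). Raw alignment scores are reported so downstream
    thresholds behave like the internal backend's.
    """
    with tempfile.TemporaryDirectory() as td:
        qf = Path(td) / "query.fa"
        sf = Path(td) / "window.fa"
        qf.write_text(f">query\n{peptide}\n")
        sf.write_text(f">window\n{window_dna}\n")
        proc = subprocess.run(
            [
                tblastn_exe, "-query", str(qf), "-subject", str(sf),
                "-outfmt", "6 sstart send sframe score", "-seg", "no",
            ],
            capture_output=True, text=True, check=True,
        )
    raw: list[SeedHit] = []
    for line in proc.stdout.splitlines():
        sstart, send, sframe, score = line.split("\t")
        sstart, send, sframe, score = int(sstart), int(send), int(sframe), float(score)
        if sframe < 0:
            continue  # window is already strand-oriented
        if score < min(min_score, SEED_SELF_CAP * self_score(peptide)):
            continue
        raw.append(SeedHit(start=sstart, end=send, frame=(sstart - 1) % 3, score=score))
    raw.sort(key=lambda h: (-h.score, h.start, h.frame))
    chosen: list[SeedHit] = []
    for hit in raw:
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: (-h.score, h.start))
    return chosen


# ---------------------------------------------------------------------------
# Smith-Waterman realignment
# ---------------------------------------------------------------------------


def smith_waterman(
    query: str,
    target: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, int, int, int, int, str, str]:
    """Affine-gap local alignment (gap of length L costs open + L*extend).

    Returns (score, q_start, q_end, t_start, t_end, aligned_query,
    aligned_target) with 1-based inclusive endpoints; a zero score yields
    empty alignment strings and endpoints (0, 0, 0, 0).
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0.0, 0, 0, 0, 0, "", ""
    qi = _aa_indices(query)
    ti = _aa_indices(target)
    S = _MATRIX[qi[:, None], ti[None, :]]

    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    F = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    # tracebacks: 0 stop, 1 diag, 2 from E, 3 from F; for E/F: 1 = opened here
    tb_H = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_E = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_F = np.zeros((n + 1, m + 1), dtype=np.int8)

    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        Si = S[i - 1]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] - open_cost
            e_ext = Ei[j - 1] - gap_extend
            if e_open >= e_ext:
                Ei[j] = e_open
                tb_E[i, j] = 1
            else:
                Ei[j] = e_ext
            f_open = Hi1[j] - open_cost
            f_ext = Fi1[j] - gap_extend
            if f_open >= f_ext:
                Fi[j] = f_open
                tb_F[i, j] = 1
            else:
                Fi[j] = f_ext
            diag = Hi1[j - 1] + Si[j - 1]
            best, tb = 0.0, 0
            if diag > best:
                best, tb = diag, 1
            if Ei[j] > best:
                best, tb = Ei[j], 2
            if Fi[j] > best:
                best, tb = Fi[j], 3
            Hi[j] = best
            tb_H[i, j] = tb

    flat = int(np.argmax(H))
    i, j = divmod(flat, m + 1)
    score = float(H[i, j])
    if score <= 0.0:
        return 0.0, 0, 0, 0, 0, "", ""
    q_end, t_end = i, j
    aq: list[str] = []
    at: list[str] = []
    state = "H"
    while True:
        if state == "H":
            tb = tb_H[i, j]
            if tb == 0:
                break
            if tb == 1:
                aq.append(query[i - 1])
                at.append(target[j - 1])
                i -= 1
                j -= 1
            elif tb == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            opened = tb_E[i, j]
            aq.append("-")
            at.append(target[j - 1])
            j -= 1
            state = "H" if opened else "E"
        else:
            opened = tb_F[i, j]
            aq.append(query[i - 1])
            at.append("-")
            i -= 1
            state = "H" if opened else "F"
    return (
        score, i + 1, q_end, j + 1, t_end,
        "".join(reversed(aq)), "".join(reversed(at)),
    )


def sw_align(
    peptide: str,
    window_dna: str,
    seed: SeedHit,
    window: SearchWindow | None = None,
    margin_codons: int = DEFAULT_MARGIN_CODONS,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ExonAlignment:
    """Realign the query to the translated region around a seed.

    The seed interval is widened by ``margin_codons`` codons on each side,
    translated in the seed frame, and locally aligned to the query. The
    aligned target span is mapped back to window nucleotides and, when a
    :class:`~exhume.detect.SearchWindow` is supplied, to reference genomic
    coordinates (strand-aware: on '-' the window was reverse-complemented, so
    window offsets count from R downward).
    """
    f = seed.frame
    prot = translate_frame(window_dna, f)
    seed_ts = (seed.start - 1 - f) // 3
    seed_te = (seed.end - f) // 3 - 1
    a0 = max(0, seed_ts - margin_codons)
    a1 = min(len(prot), seed_te + 1 + margin_codons)
    region = prot[a0:a1]

    score, qs, qe, ts, te, aq, at = smith_waterman(
        peptide, region, gap_open=gap_open, gap_extend=gap_extend
    )
    if score <= 0.0:
        aln = ExonAlignment(
            query_peptide=peptide, target_peptide=region,
            aligned_query="", aligned_target="", frame=f, score=0.0,
            window_start=seed.start, window_end=seed.end,
            identity_defined=False,
        )
        _fill_genome_coords(aln, window)
        return aln

    # Anchored full-exon extension: the optimal local core sheds terminally
    # mismatched residues, but the prediction should represent the whole exon.
    # Extend the alignment ungapped to the query termini as far as the
    # translated region allows; coverage and identity are judged on this
    # full-length alignment while `score` stays the optimal local score.
    left = min(qs - 1, ts - 1)
    right = min(len(peptide) - qe, len(region) - te)
    if left:
        aq = peptide[qs - 1 - left : qs - 1] + aq
        at = region[ts - 1 - left : ts - 1] + at
        qs, ts = qs - left, ts - left
    if right:
        aq = aq + peptide[qe : qe + right]
        at = at + region[te : te + right]
        qe, te = qe + right, te + right

    ws = f + 3 * (a0 + ts - 1) + 1
    we = f + 3 * (a0 + te - 1) + 3
    aln = ExonAlignment(
        query_peptide=peptide, target_peptide=region,
        aligned_query=aq, aligned_target=at, frame=f, score=score,
        window_start=ws, window_end=we,
        query_coverage=(qe - qs + 1) / len(peptide),
    )
    aln.pct_identity, aln.identity_defined = _identity_of_pair(aq, at)
    _fill_genome_coords(aln, window)
    return aln


def _fill_genome_coords(aln: ExonAlignment, window: SearchWindow | None) -> None:
    if window is None:
        return
    aln.chrom = window.chrom
    aln.strand = window.strand
    if window.strand == "+":
        aln.genome_start = window.L + aln.window_start - 1
        aln.genome_end = window.L + aln.window_end - 1
    else:
        aln.genome_start = window.R - aln.window_end + 1
        aln.genome_end = window.R - aln.window_start + 1


def _identity_of_pair(aq: str, at: str) -> tuple[float, bool]:
    gap_free = [(a, b) for a, b in zip(aq, at) if a != "-" and b != "-"]
    if not gap_free:
        return 0.0, False
    same = sum(1 for a, b in gap_free if a == b)
    return 100.0 * same / len(gap_free), True


def percent_identity(a: ExonAlignment) -> float:
    """Percent of gap-free alignment columns sharing the same residue.

    Columns with a gap on either side are excluded from numerator and
    denominator. With no gap-free column at all the value is reported as 0
    and the alignment is flagged (``identity_defined = False``).
    """
    pct, defined = _identity_of_pair(a.aligned_query, a.aligned_target)
    a.pct_identity = pct
    a.identity_defined = defined
    return pct


def accept_prediction(a: ExonAlignment, cfg) -> Acceptance:
    """Accept iff the alignment is a high-identity, (nearly) full-length match.

    ``cfg`` needs ``min_coverage`` (default 0.90) and ``min_identity``
    (default 35, percent). Rejection reasons are recorded.
    """
    if a.score <= 0.0:
        return Acceptance(False, "score")
    if a.query_coverage < cfg.min_coverage:
        return Acceptance(False, "coverage")
    if a.pct_identity < cfg.min_identity:
        return Acceptance(False, "identity")
    return Acceptance(True)
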