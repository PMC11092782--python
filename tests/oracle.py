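"""Independent reference implementations used only to check the package.

`enumerate_local_score` scores every possible local alignment of two peptides
by brute force: a local alignment with affine gaps is fully determined by the
ordered set of matched residue pairs, so enumerating all monotone matchings
and charging open + length * extend for every internal gap run covers the
whole search space. Exponential — only for tiny inputs.
"""

from itertools import combinations

from exhume.search import substitution_score


def enumerate_local_score(query, target, gap_open=11, gap_extend=1):
    nq, nt = len(query), len(target)
    best = 0.0
    for k in range(1, min(nq, nt) + 1):
        for qidx in combinations(range(nq), k):
            for tidx in combinations(range(nt), k):
                score = substitution_score(query[qidx[0]], target[tidx[0]])
                for a in range(1, k):
                    dq = qidx[a] - qidx[a - 1] - 1
                    dt = tidx[a] - tidx[a - 1] - 1
                    if dq:
                        score -= gap_open + gap_extend * dq
                    if dt:
                        score -= gap_open + gap_extend * dt
                    score += substitution_score(query[qidx[a]], target[tidx[a]])
                if score > best:
                    best = score
    return best


def biopython_local_score(query, target, gap_open=11, gap_extend=1):
    """Independent affine-gap local aligner (gap of length L costs open + L*extend)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    try:
        return float(aligner.score(query, target))
    except ValueError:
        return 0.0
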