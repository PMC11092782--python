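import pytest
from hypothesis import given, strategies as st

from exhume.collapse import collapse_isoforms, derive_exon_blocks
from exhume.detect import compute_search_window, find_missing_exons
from exhume.simulate import HiddenExon, SyntheticFamilySpec, generate_family

from conftest import make_alignment


def _collapsed(aln):
    return derive_exon_blocks(collapse_isoforms(aln))


def test_fully_populated_alignment_has_no_candidates():
    aln = make_alignment(
        [
            ("A", "sp1", "c", "+", None, "MKVLQR", [101, 104, 107, 110, 113, 116]),
            ("B", "sp2", "c", "+", None, "MKVLQR", [201, 204, 207, 210, 213, 216]),
        ]
    )
    assert find_missing_exons(_collapsed(aln)) == []


def test_block_missing_in_one_species(simple_alignment):
    collapsed = _collapsed(simple_alignment)
    assert collapsed.X == [(1, 4), (5, 8), (9, 12)]
    cands = find_missing_exons(collapsed)
    # middle block is gapped only in sp2; flanking blocks are <6 aa queries
    # in every species so only the 4-residue ones cannot seed a candidate
    assert len(cands) == 0  # all blocks here are 4 aa, below the 6 aa minimum


def test_candidate_with_queries_from_both_other_species():
    rows = [
        ("A", "sp1", "c1", "+", 1, "MKVLQW" + "ACDEFG" + "HIKLMN",
         [101 + 3 * i for i in range(6)] + [1001 + 3 * i for i in range(6)] + [2001 + 3 * i for i in range(6)]),
        ("B", "sp2", "c2", "+", 2, "MKVLQW" + "------" + "HIKLMN",
         [201 + 3 * i for i in range(6)] + [3001 + 3 * i for i in range(6)]),
        ("C", "sp3", "c3", "+", None, "MKVLQW" + "ACDEFG" + "HIKLMN",
         [301 + 3 * i for i in range(6)] + [4001 + 3 * i for i in range(6)] + [5001 + 3 * i for i in range(6)]),
    ]
    cands = find_missing_exons(_collapsed(make_alignment(rows)))
    assert len(cands) == 1
    c = cands[0]
    assert c.target_species == "sp2"
    assert c.block == (7, 12)
    assert [q.source_species for q in c.queries] == ["sp1", "sp3"]
    assert all(q.peptide == "ACDEFG" for q in c.queries)
    # annotation score of the sp1 query comes from its contributing isoform
    assert c.queries[0].source_annotation_score == 1


def test_block_missing_in_two_species_gives_two_candidates():
    rows = [
        ("A", "sp1", "c1", "+", None, "MKVLQW" + "ACDEFG",
         [101 + 3 * i for i in range(6)] + [1001 + 3 * i for i in range(6)]),
        ("B", "sp2", "c2", "+", None, "MKVLQW" + "------",
         [201 + 3 * i for i in range(6)]),
        ("C", "sp3", "c3", "+", None, "MKVLQW" + "------",
         [301 + 3 * i for i in range(6)]),
    ]
    cands = find_missing_exons(_collapsed(make_alignment(rows)))
    assert {(c.target_species, c.block) for c in cands} == {
        ("sp2", (7, 12)),
        ("sp3", (7, 12)),
    }
    for c in cands:
        assert [q.source_species for q in c.queries] == ["sp1"]


def test_query_peptide_strips_gaps_and_enforces_minimum():
    rows = [
        ("A", "sp1", "c1", "+", None, "MKVLQW" + "MKVLQ-R",
         [101 + 3 * i for i in range(6)] + [1001 + 3 * i for i in range(6)]),
        ("B", "sp2", "c2", "+", None, "MKVLQW" + "MKV----",
         [201 + 3 * i for i in range(6)] + [3001 + 3 * i for i in range(3)]),
        ("C", "sp3", "c3", "+", None, "MKVLQW" + "-------",
         [301 + 3 * i for i in range(6)]),
    ]
    cands = find_missing_exons(_collapsed(make_alignment(rows)))
    assert len(cands) == 1
    c = cands[0]
    assert c.target_species == "sp3"
    # sp1's block content "MKVLQ-R" -> "MKVLQR" kept; sp2's "MKV" discarded
    assert [q.peptide for q in c.queries] == ["MKVLQR"]


def one_missing_block(strand, up_coords, down_coords):
    """Target species sp2 missing the middle of three 6-aa exon blocks."""
    q1 = [101 + 3 * i for i in range(6)]
    q2 = [1001 + 3 * i for i in range(6)]
    q3 = [2001 + 3 * i for i in range(6)]
    rows = [
        ("A", "sp1", "c1", "+", None, "MKVLQW" * 3, q1 + q2 + q3),
    ]
    aligned = ("MKVLQW" if up_coords else "------") + "------" + (
        "MKVLQW" if down_coords else "------"
    )
    coords = (up_coords or []) + (down_coords or [])
    rows.append(("B", "sp2", "c2", strand, None, aligned, coords))
    collapsed = _collapsed(make_alignment(rows))
    cands = [c for c in find_missing_exons(collapsed) if c.target_species == "sp2"]
    mid = [c for c in cands if c.block == (7, 12)]
    return collapsed, mid[0]


def check_window_arithmetic(strand, up_mid, down_gap, pad):
    """L/R equal the flanking codon coordinates; one-sided fallbacks are
    exactly `pad` long before clamping; minus strand keeps L < R."""
    if up_mid is None and down_gap is None:
        return
    if strand == "+":
        up = [up_mid - 15 + 3 * i for i in range(6)] if up_mid else None
        anchor = up_mid if up_mid else 40_000
        down = (
            [anchor + down_gap + 3 * i for i in range(6)] if down_gap else None
        )
    else:
        up = [up_mid + 15 - 3 * i for i in range(6)] if up_mid else None
        anchor = up_mid if up_mid else 40_000
        down = (
            [anchor - down_gap - 3 * i for i in range(6)] if down_gap else None
        )
    collapsed, cand = one_missing_block(strand, up, down)
    w = compute_search_window(collapsed, cand, pad=pad)
    up_coord = up[-1] if up else None
    down_coord = down[0] if down else None
    if up_coord is not None and down_coord is not None:
        assert (w.L, w.R) == (min(up_coord, down_coord), max(up_coord, down_coord))
    else:
        assert w.length == pad + 1
        present = up_coord if up_coord is not None else down_coord
        assert present in (w.L, w.R)
    assert w.L < w.R
    assert w.strand == strand


class TestSearchWindow:
    def _one_missing_block(self, strand, up_coords, down_coords):
        return one_missing_block(strand, up_coords, down_coords)

    def test_both_flanks_forward(self):
        up = [10_035 + 3 * i for i in range(6)]  # last middle 10,050
        down = [14_980 + 3 * i for i in range(6)]
        collapsed, cand = self._one_missing_block("+", up, down)
        w = compute_search_window(collapsed, cand)
        assert (w.L, w.R, w.strand) == (10_050, 14_980, "+")

    def test_no_upstream_falls_back(self):
        down = [100_000 + 3 * i for i in range(6)]
        collapsed, cand = self._one_missing_block("+", None, down)
        w = compute_search_window(collapsed, cand)
        assert (w.L, w.R) == (75_000, 100_000)

    def test_no_downstream_falls_back(self):
        up = [49_985 + 3 * i for i in range(6)]  # last middle 50,000
        collapsed, cand = self._one_missing_block("+", up, None)
        w = compute_search_window(collapsed, cand)
        assert (w.L, w.R) == (50_000, 75_000)

    def test_minus_strand_inverts_order(self):
        # protein-upstream flank sits at the genomic right on the minus strand
        up = [14_995 - 3 * i for i in range(6)]  # last middle 14,980
        down = [10_050 - 3 * i for i in range(6)]
        collapsed, cand = self._one_missing_block("-", up, down)
        w = compute_search_window(collapsed, cand)
        assert (w.L, w.R, w.strand) == (10_050, 14_995 - 15, "-")
        assert w.L < w.R

    def test_clamped_to_chromosome(self):
        down = [10_000 + 3 * i for i in range(6)]
        collapsed, cand = self._one_missing_block("+", None, down)
        w = compute_search_window(collapsed, cand, chrom_length=12_000)
        assert (w.L, w.R) == (1, 10_000)

    def test_no_flank_at_all_skips(self):
        collapsed, cand = self._one_missing_block("+", None, None)
        assert compute_search_window(collapsed, cand) is None

    @given(
        strand=st.sampled_from("+-"),
        up_mid=st.one_of(st.none(), st.integers(min_value=30_000, max_value=60_000)),
        down_gap=st.one_of(st.none(), st.integers(min_value=100, max_value=20_000)),
        pad=st.sampled_from([25_000, 10_000]),
    )
    def test_window_arithmetic_properties(self, strand, up_mid, down_gap, pad):
        check_window_arithmetic(strand, up_mid, down_gap, pad)


@pytest.mark.parametrize("strands", [None, ("-", "-", "-")])
def test_window_contains_planted_exon(strands):
    """Soundness: with both flanks present the true interval lies in the window."""
    for seed in range(5):
        spec = SyntheticFamilySpec(
            seed=seed, hidden_exons=(HiddenExon(1, 1, 80.0),), strands=strands
        )
        fam = generate_family(spec)
        collapsed = _collapsed(fam.alignment)
        cands = find_missing_exons(collapsed)
        assert len(cands) == 1
        t = fam.truth.exons[0]
        w = compute_search_window(collapsed, cands[0])
        assert w.chrom == t.chrom and w.strand == t.strand
        assert w.L <= t.start and t.end <= w.R
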