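import numpy as np
import pytest

from exhume.detect import SearchWindow
from exhume.pipeline import PipelineConfig, run_family
from exhume.search import (
    ExonAlignment,
    SeedHit,
    accept_prediction,
    percent_identity,
    seed_search,
    smith_waterman,
    sw_align,
    tblastn_seed_search,
    translate_frame,
)
from exhume.simulate import (
    HiddenExon,
    SyntheticFamilySpec,
    generate_family,
    CODONS_BY_AA,
)

from oracle import biopython_local_score, enumerate_local_score

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _backtranslate(pep, rng):
    return "".join(CODONS_BY_AA[aa][int(rng.integers(len(CODONS_BY_AA[aa])))] for aa in pep)


def _random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _random_pep(n, rng):
    return "".join(AA20[i] for i in rng.integers(len(AA20), size=n))


class TestSeedSearch:
    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_exact_backtranslation_is_found_in_its_frame(self, offset):
        rng = np.random.default_rng(4)
        pep = _random_pep(20, rng)
        coding = _backtranslate(pep, rng)
        window = _random_dna(300 + offset, rng) + coding + _random_dna(300, rng)
        seeds = seed_search(pep, window)
        assert seeds, "exact match must be seeded"
        top = seeds[0]
        assert top.frame == (300 + offset) % 3
        start = 300 + offset + 1
        assert top.start <= start and top.end >= start + len(coding) - 1

    def test_random_window_yields_no_seeds_at_default_threshold(self):
        rng = np.random.default_rng(5)
        pep = _random_pep(20, rng)
        hits = sum(bool(seed_search(pep, _random_dna(2000, rng))) for _ in range(20))
        assert hits == 0

    def test_two_embedded_copies_give_two_nonoverlapping_seeds(self):
        rng = np.random.default_rng(6)
        pep = _random_pep(18, rng)
        window = (
            _random_dna(90, rng) + _backtranslate(pep, rng)
            + _random_dna(120, rng) + _backtranslate(pep, rng)
            + _random_dna(90, rng)
        )
        seeds = seed_search(pep, window)
        assert len(seeds) >= 2
        a, b = sorted(seeds[:2], key=lambda s: s.start)
        assert a.end < b.start

    def test_tblastn_backend_agrees_on_exact_match(self):
        rng = np.random.default_rng(7)
        pep = _random_pep(25, rng)
        window = _random_dna(150, rng) + _backtranslate(pep, rng) + _random_dna(150, rng)
        internal = seed_search(pep, window)
        external = tblastn_seed_search(pep, window)
        assert internal and external
        # both backends locate the same region
        ia, ea = internal[0], external[0]
        assert max(ia.start, ea.start) < min(ia.end, ea.end)


class TestSmithWaterman:
    def test_identical_sequences_align_fully(self):
        score, qs, qe, ts, te, aq, at = smith_waterman("MKVLW", "MKVLW")
        assert (qs, qe, ts, te) == (1, 5, 1, 5)
        assert aq == at == "MKVLW"

    def test_against_exhaustive_enumerator_on_tiny_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            q = _random_pep(int(rng.integers(3, 8)), rng)
            t = _random_pep(int(rng.integers(3, 11)), rng)
            assert smith_waterman(q, t)[0] == enumerate_local_score(q, t)

    def test_against_independent_aligner_on_translated_regions(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            q = _random_pep(int(rng.integers(6, 13)), rng)
            region = translate_frame(_random_dna(int(rng.integers(18, 61)), rng), 0)
            assert smith_waterman(q, region)[0] == biopython_local_score(q, region)

    def test_mkvl_vs_mkil_matches_enumerator(self):
        dna = "ATGAAAATTCTG"  # codes MKIL
        region = translate_frame(dna, 0)
        score = smith_waterman("MKVL", region)[0]
        assert score == enumerate_local_score("MKVL", region)
        expected = sum(
            (5, 5, 3, 4)  # BLOSUM62: M/M, K/K, V/I, L/L
        )
        assert score == expected


class TestSwAlign:
    def test_exact_coding_dna_gives_perfect_alignment(self):
        rng = np.random.default_rng(13)
        pep = _random_pep(30, rng)
        coding = _backtranslate(pep, rng)
        window = _random_dna(60, rng) + coding + _random_dna(60, rng)
        seed = seed_search(pep, window)[0]
        a = sw_align(pep, window, seed)
        assert a.pct_identity == 100.0
        assert a.query_coverage == 1.0
        assert (a.window_start, a.window_end) == (61, 60 + len(coding))

    def test_genome_coordinates_mapped_through_window(self):
        rng = np.random.default_rng(14)
        pep = _random_pep(12, rng)
        coding = _backtranslate(pep, rng)
        window = _random_dna(30, rng) + coding + _random_dna(30, rng)
        seed = seed_search(pep, window)[0]
        w_plus = SearchWindow("chr9", "+", L=5_001, R=5_000 + len(window))
        a = sw_align(pep, window, seed, window=w_plus)
        assert (a.genome_start, a.genome_end) == (5_031, 5_030 + len(coding))
        w_minus = SearchWindow("chr9", "-", L=5_001, R=5_000 + len(window))
        b = sw_align(pep, window, seed, window=w_minus)
        assert b.genome_end - b.genome_start == a.genome_end - a.genome_start
        assert b.genome_end == w_minus.R - a.window_start + 1

    def test_wrong_frame_alignment_rejected_downstream(self):
        rng = np.random.default_rng(15)
        pep = _random_pep(20, rng)
        coding = _backtranslate(pep, rng)
        window = _random_dna(60, rng) + coding + _random_dna(60, rng)
        good = seed_search(pep, window)[0]
        shifted = SeedHit(start=good.start + 1, end=good.end + 1,
                          frame=(good.frame + 1) % 3, score=good.score)
        a = sw_align(pep, window, shifted)
        verdict = accept_prediction(a, PipelineConfig())
        assert not verdict.accepted

    def test_interval_length_is_three_times_target_residues(self):
        rng = np.random.default_rng(16)
        pep = _random_pep(25, rng)
        window = _random_dna(40, rng) + _backtranslate(pep, rng) + _random_dna(40, rng)
        seed = seed_search(pep, window)[0]
        a = sw_align(pep, window, seed)
        target_res = len(a.aligned_target.replace("-", ""))
        assert a.window_end - a.window_start + 1 == 3 * target_res


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "aq,at,expected",
        [
            ("ACDE", "ACDE", 100.0),
            ("ACDE", "ACDK", 75.0),
            ("AC-E", "ACDE", 100.0),  # gap column excluded entirely
            ("A-CE", "AKCE", 100.0),
            ("ACDE", "AKDW", 50.0),
        ],
    )
    def test_gap_free_column_identity(self, aq, at, expected):
        a = ExonAlignment(
            query_peptide=aq.replace("-", ""), target_peptide=at.replace("-", ""),
            aligned_query=aq, aligned_target=at, frame=0, score=10.0,
            window_start=1, window_end=12,
        )
        assert percent_identity(a) == expected
        assert a.identity_defined

    def test_all_gap_columns_flagged_undefined(self):
        a = ExonAlignment(
            query_peptide="AC", target_peptide="DE",
            aligned_query="AC--", aligned_target="--DE", frame=0, score=1.0,
            window_start=1, window_end=6,
        )
        assert percent_identity(a) == 0.0
        assert not a.identity_defined


class TestAcceptance:
    def _aln(self, coverage, identity):
        n = 20
        n_match = round(n * identity / 100)
        aq = "A" * n
        at = "A" * n_match + "W" * (n - n_match)
        a = ExonAlignment(
            query_peptide=aq, target_peptide=at, aligned_query=aq,
            aligned_target=at, frame=0, score=50.0, window_start=1,
            window_end=3 * n, query_coverage=coverage,
        )
        percent_identity(a)
        return a

    def test_high_identity_full_coverage_accepted(self):
        verdict = accept_prediction(self._aln(1.0, 80.0), PipelineConfig())
        assert verdict.accepted

    def test_low_coverage_rejected(self):
        verdict = accept_prediction(self._aln(0.5, 80.0), PipelineConfig())
        assert (verdict.accepted, verdict.reason) == (False, "coverage")

    def test_low_identity_rejected(self):
        verdict = accept_prediction(self._aln(0.95, 20.0), PipelineConfig())
        assert (verdict.accepted, verdict.reason) == (False, "identity")


def test_strand_symmetry_of_recovery():
    """Planting the same family on the minus strand gives the same
    peptide-level alignment and an equivalent genomic interval."""
    results = {}
    for strands in (("+", "+", "+"), ("-", "-", "-")):
        spec = SyntheticFamilySpec(
            seed=21, strands=strands, hidden_exons=(HiddenExon(1, 1, 70.0),)
        )
        fam = generate_family(spec)
        _, preds, _ = run_family(fam.alignment, fam.genomes, fam.annotation_tracks())
        assert len(preds) == 1
        p = preds[0]
        t = fam.truth.exons[0]
        assert p.start <= t.end and p.end >= t.start
        results[strands] = (
            p.best_support.alignment.aligned_query,
            p.best_support.alignment.aligned_target,
            p.pct_identity,
            p.end - p.start,
        )
    assert results[("+", "+", "+")] == results[("-", "-", "-")]
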