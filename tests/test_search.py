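"""Substring, gapped, PSFM-site and dyad-pattern searches against
brute-force oracles."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from seqsuite.core import SequenceCollection, reverse_complement
from seqsuite.motif import psfm_from_consensus, psfm_from_sites
from seqsuite.search import (
    dyad_pattern_search,
    gapped_search,
    score_site_ri,
    site_search,
    substring_search,
)

from conftest import dna, prot


def iub_mm(pattern, window):
    from seqsuite.core import IUB_EXPANSION

    return sum(
        1 for p, s in zip(pattern, window) if not (IUB_EXPANSION[p] & IUB_EXPANSION[s])
    )


class TestSubstringSearch:
    def test_iub_pattern_matches_with_zero_mismatch(self):
        hits = substring_search(dna("ACTGTA"), "CTGW", 0)
        assert [(h.start, h.end, h.mismatches) for h in hits] == [(2, 5, 0)]

    def test_mismatch_enumeration(self):
        hits = substring_search(dna("AAATAAA"), "AAAA", 1)
        assert [(h.start, h.end) for h in hits] == [(1, 4), (2, 5), (3, 6), (4, 7)]
        assert [h.mismatches for h in hits] == [1, 1, 1, 1]

    def test_protein_matrix_scores_are_summed_entries(self, blosum62):
        hits = substring_search(prot("MKMR"), "MK", matrix=blosum62, min_matrix_score=5)
        expect = {
            1: blosum62.score("M", "M") + blosum62.score("K", "K"),
            3: blosum62.score("M", "M") + blosum62.score("K", "R"),
        }
        got = {h.start: h.score for h in hits}
        assert got == {k: v for k, v in expect.items() if v >= 5}

    def test_matrix_on_nucleic_rejected(self, blosum62):
        with pytest.raises(TypeError):
            substring_search(dna("ACGT"), "AC", matrix=blosum62)

    def test_invalid_protein_pattern_letters_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            substring_search(prot("MKLW"), "MJ")

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_both_strands(self, seed, random_dna):
        s = random_dna(500, seed=seed)
        pattern = "CTGWN"
        hits = substring_search(s, pattern, 1, strands="BOTH")
        expect = []
        rc_pat = str(Seq(pattern).reverse_complement())
        for i in range(len(s) - len(pattern) + 1):
            win = s.residues[i : i + len(pattern)]
            if iub_mm(pattern, win) <= 1:
                expect.append((i + 1, "+"))
            if iub_mm(rc_pat, win) <= 1:
                expect.append((i + 1, "-"))
        assert sorted((h.start, h.strand) for h in hits) == sorted(expect)

    def test_strand_symmetry(self, random_dna):
        s = random_dna(300, seed=3)
        fwd = substring_search(s, "CTGTTT", 1, strands="BOTH")
        rc = substring_search(reverse_complement(s), "CTGTTT", 1, strands="BOTH")
        L = len(s)
        reflected = sorted((L - h.end + 1, {"+": "-", "-": "+"}[h.strand]) for h in rc)
        assert sorted((h.start, h.strand) for h in fwd) == reflected

    def test_mismatch_relaxation_monotone(self, random_dna):
        s = random_dna(400, seed=9)
        h0 = {(h.start, h.strand) for h in substring_search(s, "ACGTA", 0)}
        h2 = {(h.start, h.strand) for h in substring_search(s, "ACGTA", 2)}
        assert h0 <= h2


class TestGappedSearch:
    def test_planted_spaced_pair(self, random_dna):
        # the canonical two-substring query with a variable 6-10 spacer
        seq = dna("TT" + "CTGT" + "ACGTACGT" + "ACAG" + "TT")
        hits = gapped_search(seq, "CTGW", "WCAG", 2, 6, 10)
        exact = [h for h in hits if h.total_score == 0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.left.start, h.spacer, h.right.start) == (3, 8, 15)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed, random_dna):
        s = random_dna(300, seed=seed + 100)
        left, right, mm, smin, smax = "CTGW", "WCAG", 2, 6, 10
        hits = gapped_search(s, left, right, mm, smin, smax)
        expect = []
        res = s.residues
        for i in range(len(res) - len(left) + 1):
            lw = res[i : i + len(left)]
            ml = iub_mm(left, lw)
            if ml > mm:
                continue
            for sp in range(smin, smax + 1):
                j = i + len(left) + sp
                if j + len(right) > len(res):
                    continue
                rw = res[j : j + len(right)]
                mr = iub_mm(right, rw)
                if ml + mr <= mm:
                    expect.append((i + 1, sp, ml + mr))
        assert sorted((h.left.start, h.spacer, int(h.total_score)) for h in hits) == sorted(expect)

    def test_fixed_spacer_equals_concatenated_pattern(self, random_dna):
        s = random_dna(400, seed=55)
        k = 7
        gap_hits = gapped_search(s, "ACG", "TGC", 1, k, k)
        concat_hits = substring_search(s, "ACG" + "N" * k + "TGC", 1)
        assert sorted(h.left.start for h in gap_hits) == sorted(
            h.start for h in concat_hits
        )

    def test_negative_spacer_rejected(self):
        with pytest.raises(ValueError):
            gapped_search(dna("ACGTACGT"), "AC", "GT", 0, -1, 2)


class TestScoreSiteRi:
    def test_consensus_of_conserved_psfm_scores_2w(self):
        p = psfm_from_sites(["ACGTAC"], pseudocount=0)
        assert score_site_ri(p, "ACGTAC", "MUTUAL_INFO_RI") == pytest.approx(12.0)

    def test_uniform_column_contributes_zero(self):
        p = psfm_from_consensus("N")
        assert score_site_ri(p, "A", "MUTUAL_INFO_RI") == pytest.approx(0.0)

    def test_zero_frequency_gives_minus_infinity_not_exception(self):
        p = psfm_from_sites(["A"], pseudocount=0)
        assert score_site_ri(p, "C") == -np.inf

    def test_ambiguous_subject_scores_background_weighted_mean(self):
        p = psfm_from_sites(["A"], pseudocount=0)
        # N over uniform background: mean f = 0.25 -> 2 + log2(0.25) = 0
        assert score_site_ri(p, "N", "MUTUAL_INFO_RI") == pytest.approx(0.0)

    @pytest.mark.parametrize("w", [3, 4])
    def test_psfm_weighted_mean_ri_equals_total_ic(self, w):
        # E_f[R_i] under the REL_ENTROPY form = total relative-entropy IC
        from seqsuite.motif import information_content

        rng = np.random.default_rng(w)
        sites = ["".join("ACGT"[k] for k in rng.integers(0, 4, w)) for _ in range(6)]
        p = psfm_from_sites(sites, pseudocount=1.0)
        total = 0.0
        for window in itertools.product("ACGT", repeat=w):
            window = "".join(window)
            prob = np.prod(
                [p.frequencies[j, "ACGT".index(c)] for j, c in enumerate(window)]
            )
            total += prob * score_site_ri(p, window, "REL_ENTROPY_RI")
        assert total == pytest.approx(information_content(p, "REL_ENTROPY")[1])


class TestSiteSearch:
    def test_consensus_window_found_with_maximal_score(self):
        p = psfm_from_sites(["CTGTAT"], pseudocount=0)
        hits = site_search(dna("AACTGTATAA"), p, threshold_bits=0.0)
        assert hits and hits[0].score == pytest.approx(12.0)
        assert (hits[0].start, hits[0].end) == (3, 8)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed, random_dna):
        s = random_dna(500, seed=seed + 200)
        rng = np.random.default_rng(seed)
        sites = ["".join("ACGT"[k] for k in rng.integers(0, 4, 6)) for _ in range(5)]
        p = psfm_from_sites(sites, pseudocount=1.0)
        hits = site_search(s, p, threshold_bits=4.0)
        expect = []
        for i in range(len(s) - 6 + 1):
            sc = score_site_ri(p, s.residues[i : i + 6])
            if sc >= 4.0:
                expect.append((i + 1, pytest.approx(sc)))
        assert [(h.start, h.score) for h in hits] == expect

    def test_palindromic_psfm_strand_hit_sets_coincide(self, random_dna):
        s = random_dna(300, seed=31)
        p = psfm_from_consensus("CTGCAG")  # reverse-complement palindrome
        hits = site_search(s, p, threshold_bits=11.0, strands="BOTH")
        plus = {h.start for h in hits if h.strand == "+"}
        minus = {h.start for h in hits if h.strand == "-"}
        assert plus == minus

    def test_impossible_threshold_warns_and_returns_empty(self):
        p = psfm_from_consensus("ACGT")
        with pytest.warns(UserWarning, match="threshold"):
            assert site_search(dna("ACGTACGT"), p, threshold_bits=100.0) == []

    def test_lower_threshold_is_superset(self, random_dna):
        s = random_dna(400, seed=13)
        p = psfm_from_sites(["ACGTT", "ACGTA", "ACCTT"], pseudocount=1.0)
        high = {(h.start, h.strand) for h in site_search(s, p, 6.0)}
        low = {(h.start, h.strand) for h in site_search(s, p, 2.0)}
        assert high <= low


class TestDyadPatternSearch:
    def test_planted_perfect_inverted_repeat_tops(self):
        half = "CTGT"
        seq = dna("GG" + half + "ATATATAT" + "ACAG" + "GG")
        hits = dyad_pattern_search(seq, half, 6, 10, "INVERTED", threshold_bits=0.0)
        best = max(hits, key=lambda h: h.total_score)
        assert best.total_score == pytest.approx(16.0)  # 2 x 8 bits
        assert (best.left.start, best.spacer) == (3, 8)

    def test_direct_search_ignores_inverted_planting(self):
        half = "CTGA"  # asymmetric half-site
        seq = dna("TT" + half + "CCCCCCCC" + "TCAG" + "TT")
        inv = dyad_pattern_search(seq, half, 8, 8, "INVERTED", threshold_bits=15.9)
        dir_ = dyad_pattern_search(seq, half, 8, 8, "DIRECT", threshold_bits=15.9)
        assert len(inv) == 1 and len(dir_) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed, random_dna):
        s = random_dna(300, seed=seed + 300)
        p = psfm_from_sites(["CTGT", "CTGT", "CAGT", "CTAT"], pseudocount=1.0)
        w = 4
        hits = dyad_pattern_search(s, p, 2, 5, "INVERTED", threshold_bits=6.0)
        res = s.residues
        expect = []
        for i in range(len(res) - w + 1):
            ls = score_site_ri(p, res[i : i + w])
            if ls < 0.0:
                continue
            for sp in range(2, 6):
                j = i + w + sp
                if j + w > len(res):
                    continue
                rs = score_site_ri(p, str(Seq(res[j : j + w]).reverse_complement()))
                if rs < 0.0:
                    continue
                if ls + rs >= 6.0:
                    expect.append((i + 1, sp, pytest.approx(ls + rs)))
        assert [(h.left.start, h.spacer, h.total_score) for h in hits] == expect

    def test_total_score_is_sum_of_halves(self, random_dna):
        s = random_dna(200, seed=17)
        hits = dyad_pattern_search(s, "NNNN", 0, 3, "DIRECT", threshold_bits=-1.0)
        for h in hits[:20]:
            assert h.total_score == pytest.approx(h.left.score + h.right.score)
            assert h.right.start == h.left.end + h.spacer + 1
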