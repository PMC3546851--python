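"""PSFM construction, information content, consensus logos, motif discovery
and string dyad discovery."""

import numpy as np
import pytest
from Bio.Seq import Seq

from seqsuite.core import SequenceCollection
from seqsuite.motif import (
    DyadOrientation,
    dyad_motif_discovery,
    gibbs_sample,
    greedy_search,
    information_content,
    psfm_from_consensus,
    psfm_from_sites,
    render_consensus_logo,
)
from seqsuite.simulate import PlantSpec, generate_planted

from conftest import dna


class TestPsfmFromSites:
    def test_unanimous_sites(self):
        p = psfm_from_sites(["AA", "AA"], pseudocount=0)
        assert p.frequencies[0, 0] == 1.0 and p.frequencies[1, 0] == 1.0
        assert p.n_sites == 2

    def test_split_column(self):
        p = psfm_from_sites(["A", "C"], pseudocount=0)
        assert p.frequencies[0].tolist() == [0.5, 0.5, 0.0, 0.0]

    def test_pseudocount_formula(self):
        # one site 'A', alpha=1, uniform background: (1 + 0.25)/2
        p = psfm_from_sites(["A"], pseudocount=1)
        assert p.frequencies[0, 0] == pytest.approx(0.625)
        assert p.frequencies[0, 1] == pytest.approx(0.125)

    def test_ragged_sites_named(self):
        with pytest.raises(ValueError, match="site_2"):
            psfm_from_sites(["ACG", "AC"], pseudocount=0)

    def test_rows_sum_to_one_with_any_pseudocount(self):
        p = psfm_from_sites(["ACGT", "AAAA", "ACGG"], pseudocount=2.5)
        assert np.allclose(p.frequencies.sum(axis=1), 1.0)


class TestPsfmFromConsensus:
    @pytest.mark.parametrize(
        "cons,col,expected",
        [
            ("R", 0, [0.5, 0.0, 0.5, 0.0]),
            ("N", 0, [0.25, 0.25, 0.25, 0.25]),
            ("ACGT", 2, [0.0, 0.0, 1.0, 0.0]),
        ],
    )
    def test_expansion_mass(self, cons, col, expected):
        p = psfm_from_consensus(cons)
        assert p.frequencies[col].tolist() == pytest.approx(expected)

    def test_invalid_character_position(self):
        with pytest.raises(ValueError, match="position 2"):
            psfm_from_consensus("AOC")


class TestInformationContent:
    def test_conserved_dna_column_is_two_bits(self):
        p = psfm_from_sites(["A"], pseudocount=0)
        per, total = information_content(p, "MUTUAL_INFO")
        assert per[0] == pytest.approx(2.0)
        assert total == pytest.approx(2.0)

    def test_uniform_column_is_zero_both_methods(self):
        p = psfm_from_consensus("N")
        for method in ("MUTUAL_INFO", "REL_ENTROPY"):
            assert information_content(p, method)[1] == pytest.approx(0.0)

    def test_half_split_column_is_one_bit(self):
        p = psfm_from_consensus("R")  # f = (0.5, 0, 0.5, 0), uniform background
        for method in ("MUTUAL_INFO", "REL_ENTROPY"):
            assert information_content(p, method)[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_methods_coincide_under_uniform_background(self, seed):
        rng = np.random.default_rng(seed)
        sites = ["".join("ACGT"[k] for k in rng.integers(0, 4, 6)) for _ in range(8)]
        p = psfm_from_sites(sites, pseudocount=1.0)
        mi = information_content(p, "MUTUAL_INFO")[1]
        kl = information_content(p, "REL_ENTROPY")[1]
        assert abs(mi - kl) < 1e-9

    def test_total_bounded(self):
        rng = np.random.default_rng(0)
        sites = ["".join("ACGT"[k] for k in rng.integers(0, 4, 10)) for _ in range(5)]
        p = psfm_from_sites(sites, pseudocount=0.5)
        _, total = information_content(p)
        assert 0.0 <= total <= 10 * 2.0

    def test_rel_entropy_zero_background_rejected(self):
        p = psfm_from_sites(["A"], pseudocount=0, background=np.array([0.0, 0.5, 0.25, 0.25]))
        with pytest.raises(ValueError, match="background"):
            information_content(p, "REL_ENTROPY")


class TestConsensusLogo:
    def test_fully_conserved_motif_tops_the_scale(self):
        logo = render_consensus_logo(psfm_from_sites(["ACGT"], pseudocount=0), rows=8)
        lines = logo.rendering.splitlines()
        assert lines[0].startswith("2.0|")
        assert "ACGT" in lines[0]  # all letters on the top row
        assert lines[-1].strip() == "ACGT"  # flat consensus beneath

    def test_proportional_placement(self):
        # IC = (2.0, 1.0) bits -> top row and halfway row of a 4-row grid
        p = psfm_from_sites(["AR"], pseudocount=0)
        lines = render_consensus_logo(p, rows=4).rendering.splitlines()
        assert "A" in lines[0]
        assert "A" in lines[4 - 2].replace("|", "")  # row at height 2 of 4

    def test_zero_information_sits_on_bottom_row(self):
        lines = render_consensus_logo(psfm_from_consensus("NN"), rows=5).rendering.splitlines()
        assert lines[4].endswith("AA")  # bottom grid row; consensus ties -> A
        assert lines[5].strip() == "AA"

    def test_consensus_tie_break_by_alphabet_order(self):
        assert psfm_from_consensus("RYN").consensus() == "ACA"

    def test_deterministic(self):
        p = psfm_from_sites(["ACGT", "AAGT"], pseudocount=1)
        assert render_consensus_logo(p).rendering == render_consensus_logo(p).rendering


def _planted(seed, w=8, n=10, length=100):
    rng = np.random.default_rng(seed)
    motif = "".join("ACGT"[k] for k in rng.integers(0, 4, w))
    return generate_planted(PlantSpec(motif=motif, n_sequences=n, length=length, seed=seed))


class TestDiscovery:
    @pytest.mark.parametrize("algo", [gibbs_sample, greedy_search])
    def test_fixed_seed_is_reproducible(self, algo):
        coll, _ = _planted(42)
        a = algo(coll, 8, iterations=3, seed=5)
        b = algo(coll, 8, iterations=3, seed=5)
        assert a.site_positions == b.site_positions
        assert a.information_content == b.information_content

    def test_single_sequence_returns_a_width_w_site(self):
        coll = SequenceCollection([dna("ACGTACGTACGT", "only")])
        res = gibbs_sample(coll, 5, iterations=2, seed=0)
        pos, strand = res.site_positions["only"]
        assert 1 <= pos <= 8 and strand == "+"
        assert len(res.sites[0]) == 5

    def test_two_identical_sequences_reach_full_conservation(self):
        coll = SequenceCollection([dna("TTACGTACGGTT", "a"), dna("TTACGTACGGTT", "b")])
        res = greedy_search(coll, 6, iterations=5, seed=1)
        assert res.information_content == pytest.approx(12.0)  # 2 bits x 6 columns

    def test_width_exceeding_sequence_rejected(self):
        coll = SequenceCollection([dna("ACGT", "short")])
        with pytest.raises(ValueError, match="short"):
            gibbs_sample(coll, 10, iterations=1)

    @pytest.mark.parametrize("algo", [gibbs_sample, greedy_search])
    def test_more_restarts_never_decrease_information(self, algo):
        coll, _ = _planted(7)
        ic1 = algo(coll, 8, iterations=1, seed=3).information_content
        ic5 = algo(coll, 8, iterations=5, seed=3).information_content
        assert ic5 >= ic1 - 1e-12

    def test_result_psfm_reproducible_from_sites(self):
        coll, _ = _planted(11)
        res = gibbs_sample(coll, 8, iterations=3, seed=2)
        rebuilt = psfm_from_sites(res.sites, pseudocount=0)
        assert np.allclose(rebuilt.frequencies, res.psfm.frequencies)
        assert information_content(rebuilt, res.method)[1] == pytest.approx(
            res.information_content
        )

    def test_both_strands_finds_reverse_planted_motif(self):
        # discovery over both strands can legitimately report the motif in
        # either global orientation; the planted intervals must still be hit
        coll, truth = generate_planted(
            PlantSpec(motif="ACGGATCC", strand_policy="both", seed=5)
        )
        res = gibbs_sample(coll, 8, iterations=20, seed=4, both_strands=True)
        correct = sum(
            1 for i, (pos, _) in truth.items() if res.site_positions[i][0] == pos
        )
        assert correct >= 9


def dyad_oracle(res, dyad_len, spacer, max_mm, d_tol, s_tol, orientation):
    """Brute-force double loop over every placement (Biopython revcomp)."""
    out = []
    L = len(res)
    oris = (
        ["DIRECT", "INVERTED"] if orientation == "BOTH" else [orientation]
    )
    for i in range(L):
        for ell in range(dyad_len - d_tol, dyad_len + d_tol + 1):
            for s in range(spacer - s_tol, spacer + s_tol + 1):
                j = i + ell + s
                if j + ell > L:
                    continue
                left, right = res[i : i + ell], res[j : j + ell]
                for ori in oris:
                    tgt = right if ori == "DIRECT" else str(Seq(right).reverse_complement())
                    mm = sum(1 for a, b in zip(left, tgt) if a != b)
                    if mm <= max_mm:
                        out.append((i + 1, j + 1, ell, s, mm, ori))
    return sorted(out)


class TestDyadDiscovery:
    def test_planted_inverted_repeat_found_exactly_once(self, random_dna):
        # CTGT + 8 bp spacer + ACAG (revcomp of CTGT): the classic SOS-box shape
        seq = dna("CTGT" + "AAAAAAAA" + "ACAG")
        hits = dyad_motif_discovery(seq, 4, 8, max_mismatch=0, orientation="INVERTED")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start_left, h.start_right, h.spacer, h.mismatches) == (1, 13, 8, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, random_dna):
        s = random_dna(200, seed=seed)
        hits = dyad_motif_discovery(s, 4, 8, max_mismatch=2, d_tol=1, s_tol=1,
                                    orientation="BOTH")
        got = sorted(
            (h.start_left, h.start_right, h.length, h.spacer, h.mismatches,
             h.orientation.value)
            for h in hits
        )
        assert got == dyad_oracle(s.residues, 4, 8, 2, 1, 1, "BOTH")

    def test_mismatch_relaxation_is_monotone(self, random_dna):
        s = random_dna(300, seed=77)
        strict = {
            (h.start_left, h.start_right, h.length, h.spacer, h.orientation)
            for h in dyad_motif_discovery(s, 4, 8, 0, orientation="BOTH")
        }
        loose = {
            (h.start_left, h.start_right, h.length, h.spacer, h.orientation)
            for h in dyad_motif_discovery(s, 4, 8, 2, orientation="BOTH")
        }
        assert strict <= loose

    def test_negative_spacer_tolerance_rejected(self):
        with pytest.raises(ValueError, match="spacer"):
            dyad_motif_discovery(dna("ACGTACGTACGT"), 4, 1, s_tol=2)

    def test_short_half_site_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            dyad_motif_discovery(dna("ACGTACGT"), 3, 2, d_tol=1)
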