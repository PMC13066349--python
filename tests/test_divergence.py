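"""NG86 counting, Jukes–Cantor correction, DI aggregation, classification."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodi.divergence import (
    SENSE_CODONS,
    PairwiseCodonAlignment,
    classify_selection,
    compute_di,
    count_differences,
    count_sites,
    estimate_dnds,
    jukes_cantor,
)

import oracles

codons = st.sampled_from(SENSE_CODONS)


class TestCountSites:
    @pytest.mark.parametrize(
        "codon, n, s",
        [
            ("TTT", 8 / 3, 1 / 3),  # Phe: one synonymous third-position change
            ("GCT", 2.0, 1.0),      # Ala: fully synonymous third position
            ("ATG", 3.0, 0.0),      # Met: no synonymous neighbour
        ],
    )
    def test_examples(self, codon, n, s):
        assert count_sites(codon) == pytest.approx((n, s))

    def test_rejects_stop_and_gap(self):
        with pytest.raises(ValueError, match="stop"):
            count_sites("TAA")
        with pytest.raises(ValueError, match="codon"):
            count_sites("A-G")

    def test_fractions_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            n, s = count_sites(codon)
            assert n + s == pytest.approx(3.0, abs=1e-12)


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a, b, nd, sd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTC", 0.0, 1.0),  # Phe->Phe, silent third position
        ],
    )
    def test_examples(self, a, b, nd, sd):
        assert count_differences(a, b) == (nd, sd)

    def test_two_step_pathway_average(self):
        # TTT -> GTC: orderings via GTT (Phe->Val->Val: 1N+1S) and TTC
        # (Phe->Phe->Val: 1S+1N); average is (1, 1)
        nd, sd = count_differences("TTT", "GTC")
        assert (nd, sd) == pytest.approx((1.0, 1.0))
        assert nd + sd == 2.0

    def test_exhaustive_oracle_equivalence(self):
        """Pathway averaging agrees with brute-force enumeration on all
        61 x 61 sense-codon pairs, and counts sum to the codon Hamming
        distance."""
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                got = count_differences(a, b)
                want = oracles.pathway_differences(a, b)
                assert got == pytest.approx(want, abs=1e-12), (a, b)
                hamming = sum(x != y for x, y in zip(a, b))
                assert sum(got) == pytest.approx(hamming, abs=1e-12)

    def test_sites_oracle_equivalence(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon) == pytest.approx(
                oracles.site_fractions(codon), abs=1e-12
            )


class TestEstimateDnDs:
    def test_single_synonymous_difference(self):
        aln = PairwiseCodonAlignment.from_sequences("g", "s", "TTTGCTAAA", "TTCGCTAAA")
        e = estimate_dnds(aln)
        assert e.Sd == 1.0 and e.Nd == 0.0
        assert e.S_sites == pytest.approx(5 / 3)
        assert e.pS == pytest.approx(0.6)
        assert e.dS == pytest.approx(-0.75 * math.log(1 - 0.8), abs=1e-9)
        assert e.dN == 0.0
        assert e.ratio == 0.0

    def test_identical_pair_ratio_undefined(self):
        aln = PairwiseCodonAlignment.from_sequences("g", "s", "TTTGCT", "TTTGCT")
        e = estimate_dnds(aln)
        assert e.dN == e.dS == 0.0
        assert e.ratio is None

    def test_nonsynonymous_only_ratio_undefined(self):
        # Met codon changed at position 1 only: dS stays 0, so no ratio
        aln = PairwiseCodonAlignment.from_sequences("g", "s", "ATGGCT", "CTGGCT")
        e = estimate_dnds(aln)
        assert e.Sd == 0.0 and e.Nd > 0
        assert e.ratio is None

    def test_saturation_is_error(self):
        # every third position silently substituted: pS = 1 >= 0.75
        seq_a = "GCT" * 4
        seq_b = "GCC" * 4
        aln = PairwiseCodonAlignment.from_sequences("g", "s", seq_a, seq_b)
        with pytest.raises(ValueError, match="saturation"):
            estimate_dnds(aln)

    def test_gapped_columns_discarded(self):
        aln = PairwiseCodonAlignment.from_sequences("g", "s", "TTT---GCTAAA", "TTCAAAGCTAAA")
        e = estimate_dnds(aln)
        assert e.n_codons == 3 and e.n_discarded == 1

    def test_zero_usable_columns_is_error(self):
        aln = PairwiseCodonAlignment.from_sequences("g", "s", "---", "AAA")
        with pytest.raises(ValueError, match="zero usable"):
            estimate_dnds(aln)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            PairwiseCodonAlignment.from_sequences("g", "s", "TAAGCT", "TTAGCT")

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(ValueError, match="length"):
            PairwiseCodonAlignment.from_sequences("g", "s", "TTT", "TTTTTT")
        with pytest.raises(ValueError, match="divisible by 3"):
            PairwiseCodonAlignment.from_sequences("g", "s", "TTTT", "TTTT")

    @given(st.lists(st.tuples(codons, codons), min_size=1, max_size=30), st.randoms())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_column_order_invariance(self, cols, rnd):
        """Swapping the two sequences or permuting codon columns leaves
        every NG86 count unchanged; sites always total 3 per column."""
        try:
            e = estimate_dnds(PairwiseCodonAlignment("g", "s", tuple(cols)))
        except ValueError:  # saturated random pair: correction undefined
            return
        swapped = estimate_dnds(
            PairwiseCodonAlignment("g", "s", tuple((b, a) for a, b in cols))
        )
        shuffled_cols = list(cols)
        rnd.shuffle(shuffled_cols)
        shuffled = estimate_dnds(PairwiseCodonAlignment("g", "s", tuple(shuffled_cols)))
        for other in (swapped, shuffled):
            assert other.N_sites == pytest.approx(e.N_sites)
            assert other.S_sites == pytest.approx(e.S_sites)
            assert other.Nd == pytest.approx(e.Nd)
            assert other.Sd == pytest.approx(e.Sd)
        assert e.N_sites + e.S_sites == pytest.approx(3 * len(cols), abs=1e-9)


class TestJukesCantor:
    def test_zero_and_monotone(self):
        assert jukes_cantor(0.0) == 0.0
        grid = [0.0, 0.1, 0.3, 0.5, 0.7]
        corrected = [jukes_cantor(p) for p in grid]
        assert corrected == sorted(corrected)
        assert all(c >= p for p, c in zip(grid, corrected))

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturation"):
            jukes_cantor(0.75)


class TestComputeDi:
    @pytest.mark.parametrize(
        "ratios, di, n_used",
        [
            ({"a": 0.2, "b": 0.2, "c": 0.2, "d": 0.2}, 0.2, 4),
            ({"a": 0.1, "b": 0.3}, 0.2, 2),
            ({"a": 0.4, "b": None, "c": 0.2}, 0.3, 2),  # dS=0 pair excluded
        ],
    )
    def test_mean_of_defined_ratios(self, ratios, di, n_used):
        rec = compute_di(ratios, gene_id="g")
        assert rec.di == pytest.approx(di)
        assert rec.n_used == n_used

    def test_all_undefined_gives_missing_di(self):
        rec = compute_di({"a": None, "b": None}, gene_id="g")
        assert rec.di is None
        assert rec.n_used == 0
        assert rec.selection_class == "undefined"

    def test_duplicate_species_is_error(self):
        a1 = estimate_dnds(PairwiseCodonAlignment.from_sequences("g", "sp", "TTTGCTAAA", "TTCGCTAAA"))
        with pytest.raises(ValueError, match="duplicate"):
            compute_di([a1, a1])


class TestClassifySelection:
    @pytest.mark.parametrize(
        "di, expected",
        [
            (1.84, "diversifying"),
            (1.0, "neutral"),
            (0.026, "stabilizing"),
            (None, "undefined"),
            (0.9, "neutral"),   # band bounds are inclusive
            (1.1, "neutral"),
        ],
    )
    def test_examples(self, di, expected):
        assert classify_selection(di) == expected

    def test_negative_di_is_error(self):
        with pytest.raises(ValueError, match=">= 0"):
            classify_selection(-0.1)

    def test_configurable_band(self):
        assert classify_selection(0.95, neutrality_band=(0.99, 1.01)) == "stabilizing"
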