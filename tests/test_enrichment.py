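"""Expected counts, chi-square goodness of fit, DI shares, binomial tail."""

from math import comb

import numpy as np
import pytest
from scipy import stats

from phylodi.enrichment import (
    binomial_tail,
    di_histogram,
    enrichment_test,
    expected_count,
    gof_chi2,
    partition_2x2_test,
    round_half_up,
    significance_tier,
    threshold_share,
)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "n, b_in, b_total, expected",
        [
            (80, 3203, 19504, 13.14),
            (67, 152, 420, 24.25),
            (10, 0, 100, 0.0),
        ],
    )
    def test_examples(self, n, b_in, b_total, expected):
        assert round(expected_count(n, b_in, b_total), 2) == expected

    def test_zero_background_total_is_error(self):
        with pytest.raises(ValueError, match="background_total"):
            expected_count(10, 0, 0)

    def test_expected_sums_to_n_over_categories(self, paper_fixture):
        """Expected counts across all 16 age categories total the set size."""
        universe = paper_fixture.universe
        counts = universe["pai"].value_counts()
        total = len(universe)
        n = 80
        acc = sum(expected_count(n, int(counts.get(r, 0)), total) for r in range(1, 17))
        assert acc == pytest.approx(n, abs=1e-9)


class TestGofChi2:
    def test_zero_when_observed_equals_expected(self):
        chi2, df, p = gof_chi2(20, 20.0, 80)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    @pytest.mark.parametrize(
        "observed, expected, n",
        [(37, 13.14, 80), (35, 24.25, 67), (45, 35.8, 80), (38, 27.8, 67), (6, 2.29, 13)],
    )
    def test_matches_scipy_two_cell_chisquare(self, observed, expected, n):
        """Closed form equals the generic two-cell chi-square computation."""
        chi2, _, p = gof_chi2(observed, expected, n)
        ref = stats.chisquare([observed, n - observed], [expected, n - expected])
        assert chi2 == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_p_decreases_with_deviation(self):
        ps = [gof_chi2(obs, 20.0, 80)[2] for obs in (22, 26, 32, 40)]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_expectation_is_error(self):
        with pytest.raises(ValueError, match="expected"):
            gof_chi2(5, 0.0, 10)
        with pytest.raises(ValueError, match="expected"):
            gof_chi2(5, 10.0, 10)

    def test_tier_strings(self):
        assert significance_tier(0.0004) == "p < 0.001"
        assert significance_tier(0.004) == "p < 0.01"
        assert significance_tier(0.04) == "p < 0.05"
        assert significance_tier(0.2) == "ns"


class TestEnrichmentTest:
    def test_direction_and_fields(self):
        r = enrichment_test("s", "bg", "PAI=6", observed=37, n=80,
                            background_in=3203, background_total=19504)
        assert r.direction == "enriched"
        assert round(r.expected, 2) == 13.14
        assert r.tier == "p < 0.001"
        d = enrichment_test("s", "bg", "PAI=1", observed=2, n=80,
                            background_in=6350, background_total=19504)
        assert d.direction == "depleted"


class TestPartition2x2:
    class G:
        def __init__(self, low, dev):
            self.low, self.dev = low, dev

    def make_genes(self, a, b, c, d):
        """a: low&dev, b: low&other, c: high&dev, d: high&other."""
        return (
            [self.G(True, True)] * a + [self.G(True, False)] * b
            + [self.G(False, True)] * c + [self.G(False, False)] * d
        )

    def test_margin_preservation_and_expecteds(self):
        genes = self.make_genes(18, 27, 5, 30)
        obs, exp, chi2, df, p = partition_2x2_test(genes, lambda g: g.low, lambda g: g.dev)
        assert obs.tolist() == [[18, 27], [5, 30]]
        assert exp.sum(axis=1) == pytest.approx(obs.sum(axis=1))
        assert exp.sum(axis=0) == pytest.approx(obs.sum(axis=0))
        assert np.round(exp, 2).tolist() == [[12.94, 32.06], [10.06, 24.94]]
        # hand-summed four-cell chi-square as oracle
        hand = sum(
            (o - e) ** 2 / e
            for o, e in zip([18, 27, 5, 30], [12.9375, 32.0625, 10.0625, 24.9375])
        )
        assert chi2 == pytest.approx(hand)
        assert df == 1
        assert p < 0.05

    def test_independent_table_gives_zero(self):
        genes = self.make_genes(10, 10, 10, 10)
        _, _, chi2, _, p = partition_2x2_test(genes, lambda g: g.low, lambda g: g.dev)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_is_error(self):
        genes = self.make_genes(5, 5, 0, 0)
        with pytest.raises(ValueError, match="margin"):
            partition_2x2_test(genes, lambda g: g.low, lambda g: g.dev)


class TestDiShares:
    def test_threshold_inclusive(self):
        count, percent = threshold_share([0.25, 0.25, 0.3, 0.1], 0.25)
        assert count == 3
        assert percent == pytest.approx(75.0)

    def test_all_above_cut(self):
        assert threshold_share([0.5, 0.9], 0.25) == (0, 0.0)

    def test_printed_share(self):
        count, percent = threshold_share([0.1] * 45 + [0.5] * 35, 0.25)
        assert count == 45
        assert round_half_up(percent, 1) == 56.3

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty input"):
            threshold_share([], 0.25)

    def test_histogram_counts(self):
        edges, counts = di_histogram([0.01, 0.06, 0.07, 0.3], bin_width=0.05)
        assert counts.sum() == 4
        assert counts[0] == 1 and counts[1] == 2

    def test_histogram_empty_is_error(self):
        with pytest.raises(ValueError, match="empty input"):
            di_histogram([])


class TestBinomialTail:
    def test_bounds(self):
        assert binomial_tail(0, 10, 0.3) == 1.0
        assert binomial_tail(10, 10, 0.3) == pytest.approx(0.3**10)

    def test_matches_direct_summation(self):
        k, n, p = 8, 11, 0.1642
        direct = sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
        assert binomial_tail(k, n, p) == pytest.approx(direct, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="k"):
            binomial_tail(12, 11, 0.5)
        with pytest.raises(ValueError, match="p"):
            binomial_tail(2, 11, 0.0)
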