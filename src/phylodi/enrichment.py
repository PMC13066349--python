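"""Observed-vs-expected enrichment over gene-set partitions.

For a study set of n genes and a background set, the expected number of
study genes in a category (say, PAI = 6, or DI ≤ 0.25) is n times the
background proportion in that category.  Observed and expected are
compared with a 1-df chi-square goodness of fit over the two cells
in/out of the category, without continuity correction; a 2×2 variant
tests independence of two binary partitions of the same set (also 1 df).
Significance is reported both as the exact p-value and as the smallest
conventional tier exceeded (p < 0.001 / 0.01 / 0.05), mirroring how such
results are usually printed.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "ALPHA_TIERS",
    "expected_count",
    "gof_chi2",
    "significance_tier",
    "enrichment_test",
    "partition_2x2_test",
    "di_histogram",
    "threshold_share",
    "round_half_up",
    "binomial_tail",
]

ALPHA_TIERS: tuple[float, ...] = (0.001, 0.01, 0.05)


@dataclass(frozen=True)
class EnrichmentResult:
    """One observed-vs-expected comparison of a set against a background."""

    set_name: str
    background_name: str
    category: str
    observed: int
    expected: float
    n: int
    chi2: float
    df: int
    p_value: float
    tier: str
    direction: str


def expected_count(n: int, background_in: int, background_total: int) -> float:
    """Expected category count: n × background_in / background_total."""
    if background_total <= 0:
        raise ValueError(f"background_total must be > 0, got {background_total}")
    if not 0 <= background_in <= background_total:
        raise ValueError(
            f"background_in must be in [0, {background_total}], got {background_in}"
        )
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return n * background_in / background_total


def gof_chi2(observed: int, expected: float, n: int) -> tuple[float, int, float]:
    """Two-cell 1-df goodness-of-fit chi-square, no continuity correction.

    chi2 = (obs − exp)²/exp + ((n−obs) − (n−exp))²/(n−exp); p from the
    chi-square distribution with 1 df.  Degenerate expectations (0 or n)
    are errors — the complementary cell would be empty.
    """
    if not 0 < expected < n:
        raise ValueError(f"expected must be strictly inside (0, {n}), got {expected}")
    if not 0 <= observed <= n:
        raise ValueError(f"observed must be in [0, {n}], got {observed}")
    diff2 = (observed - expected) ** 2
    chi2 = diff2 / expected + diff2 / (n - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def significance_tier(p: float, tiers: Sequence[float] = ALPHA_TIERS) -> str:
    """Smallest conventional alpha exceeded by p, e.g. "p < 0.001"; "ns" if none."""
    for alpha in sorted(tiers):
        if p < alpha:
            return f"p < {alpha:g}"
    return "ns"


def enrichment_test(
    set_name: str,
    background_name: str,
    category: str,
    observed: int,
    n: int,
    background_in: int,
    background_total: int,
) -> EnrichmentResult:
    """Full observed-vs-expected comparison for one set and category."""
    expected = expected_count(n, background_in, background_total)
    chi2, df, p = gof_chi2(observed, expected, n)
    if observed > expected:
        direction = "enriched"
    elif observed < expected:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentResult(
        set_name=set_name,
        background_name=background_name,
        category=category,
        observed=observed,
        expected=expected,
        n=n,
        chi2=chi2,
        df=df,
        p_value=p,
        tier=significance_tier(p),
        direction=direction,
    )


def partition_2x2_test(
    genes: Iterable,
    row_predicate: Callable,
    col_predicate: Callable,
) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """Chi-square independence test of two binary partitions of one set.

    Rows split the genes by ``row_predicate`` (True first), columns by
    ``col_predicate``.  Expected cells come from the margins under
    independence; chi2 sums (obs − exp)²/exp over the four cells with
    1 df and no continuity correction.  Returns (observed 2×2,
    expected 2×2, chi2, df, p).
    """
    table = np.zeros((2, 2))
    for g in genes:
        i = 0 if row_predicate(g) else 1
        j = 0 if col_predicate(g) else 1
        table[i, j] += 1
    row_margins = table.sum(axis=1)
    col_margins = table.sum(axis=0)
    total = table.sum()
    if total == 0 or (row_margins == 0).any() or (col_margins == 0).any():
        raise ValueError(f"zero margin in 2x2 table {table.tolist()}")
    expected = np.outer(row_margins, col_margins) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return table, expected, chi2, 1, p


def di_histogram(
    di_values: Iterable[float], bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bin DI values into fixed-width bins from 0; returns (edges, counts)."""
    values = np.asarray(list(di_values), dtype=float)
    if values.size == 0:
        raise ValueError("empty input: DI histogram undefined")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if (values < 0).any():
        raise ValueError("DI values must be >= 0")
    n_bins = int(np.ceil(values.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def threshold_share(di_values: Iterable[float], cut: float = 0.25) -> tuple[int, float]:
    """Count and percentage of values at or below ``cut`` (inclusive)."""
    values = list(di_values)
    if not values:
        raise ValueError("empty input: threshold share undefined")
    if cut <= 0:
        raise ValueError(f"cut must be > 0, got {cut}")
    count = sum(1 for v in values if v <= cut)
    return count, 100.0 * count / len(values)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for displayed percentages (56.25 → 56.3).

    Python's builtin round is half-even, which disagrees with the usual
    reporting convention exactly at ties.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact binomial upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))
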