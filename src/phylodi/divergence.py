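"""Pairwise dN/dS estimation (Nei–Gojobori counting) and divergence index.

The divergence index (DI) of a gene is the arithmetic mean of pairwise
dN/dS ratios between the focal (human) coding sequence and its orthologs
in a small panel of closely related hominids (chimpanzee, bonobo, gorilla,
Sumatran orangutan by default).  DI well below 1 indicates strong
stabilizing (purifying) selection, DI near 1 is consistent with neutral
evolution, and DI above 1 suggests diversifying (driving) selection.

Each pairwise ratio is estimated with the Nei–Gojobori (1986) counting
method: synonymous/nonsynonymous site fractions are tallied per codon,
observed differences are averaged over all minimal mutational pathways
between the two codons (pathways through stop codons excluded), and the
raw proportions are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4)·ln(1 - 4p/3).

A pair with dS = 0 has an undefined ratio and is excluded from the DI
mean — common between hominids, where many genes show no synonymous
change at all.  If every pair of a gene is excluded its DI is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "DEFAULT_COMPARATORS",
    "DEFAULT_NEUTRALITY_BAND",
    "PairwiseCodonAlignment",
    "DnDsEstimate",
    "DIRecord",
    "count_sites",
    "count_differences",
    "estimate_dnds",
    "compute_di",
    "classify_selection",
    "jukes_cantor",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_AA))
_BASES = "ACGT"

# the four hominid comparator species of the DI definition
DEFAULT_COMPARATORS: tuple[str, ...] = (
    "Pan troglodytes",
    "Pan paniscus",
    "Gorilla gorilla gorilla",
    "Pongo abelii",
)

DEFAULT_NEUTRALITY_BAND: tuple[float, float] = (0.9, 1.1)


def _check_sense(codon: str) -> str:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an ungapped DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon!r}")
    return codon


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site fractions of one sense codon.

    At each of the three positions the synonymous fraction is the number of
    single-nucleotide changes producing a sense codon for the same amino
    acid, divided by the number of changes producing any sense codon (stop
    neighbours do not enter the denominator).  Fractions sum to 3.
    """
    _check_sense(codon)
    aa = _AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        sense = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            sense += 1
            if _AA[neighbour] == aa:
                syn += 1
        if sense:
            s_total += syn / sense
    return 3.0 - s_total, s_total


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous difference counts between two codons.

    Counts are averaged over all minimal mutational pathways from
    ``codon_a`` to ``codon_b`` (one pathway per ordering of the differing
    positions), classifying each single-nucleotide step as synonymous or
    not.  Pathways whose intermediate codons are stops are excluded; if
    every pathway is excluded, the average falls back to all pathways.
    The two counts always sum to the number of differing positions.
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        nd = sd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if _AA[current] == _AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return nd, sd

    def walk_any(order: tuple[int, ...]) -> tuple[float, float]:
        # fallback path classification ignoring the stop exclusion; a step
        # into or out of a stop codon is counted as nonsynonymous
        nd = sd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if (
                current not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _AA[current] == _AA[nxt]
            ):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return nd, sd

    results = [r for r in map(walk, permutations(diff_positions)) if r is not None]
    if not results:
        results = [walk_any(order) for order in permutations(diff_positions)]
    nd = sum(r[0] for r in results) / len(results)
    sd = sum(r[1] for r in results) / len(results)
    return nd, sd


@dataclass(frozen=True)
class PairwiseCodonAlignment:
    """A codon-aligned pair: focal CDS vs. one ortholog.

    ``columns`` holds aligned codon pairs over the alphabet {A, C, G, T, -}.
    Both rows have the same codon length and neither ungapped sequence may
    contain an internal stop codon.
    """

    gene_id: str
    species_label: str
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for a, b in self.columns:
            if len(a) != 3 or len(b) != 3:
                raise ValueError(f"non-triplet column ({a!r}, {b!r}) in {self.gene_id}")
        for which in (0, 1):
            for a_b in self.columns:
                codon = a_b[which]
                if "-" not in codon and codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {codon} in {self.gene_id}/{self.species_label}"
                    )

    @classmethod
    def from_sequences(
        cls, gene_id: str, species_label: str, seq_a: str, seq_b: str
    ) -> "PairwiseCodonAlignment":
        seq_a, seq_b = seq_a.upper(), seq_b.upper()
        if len(seq_a) != len(seq_b):
            raise ValueError(
                f"aligned sequences differ in length for {gene_id}: "
                f"{len(seq_a)} vs {len(seq_b)}"
            )
        if len(seq_a) % 3:
            raise ValueError(
                f"alignment length {len(seq_a)} not divisible by 3 for {gene_id}"
            )
        cols = tuple(
            (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
        )
        return cls(gene_id, species_label, cols)

    def usable_columns(self) -> list[tuple[str, str]]:
        """Columns with both codons fully A/C/G/T (gap/ambiguity-free)."""
        ok = lambda c: len(c) == 3 and all(b in _BASES for b in c)
        return [(a, b) for a, b in self.columns if ok(a) and ok(b)]


@dataclass(frozen=True)
class DnDsEstimate:
    """NG86 per-pair counts and Jukes–Cantor-corrected rates.

    ``ratio`` is ``None`` (undefined) when dS = 0.  ``n_codons`` is the
    number of usable (gap- and ambiguity-free) codon columns;
    ``n_discarded`` the number dropped before counting.
    """

    gene_id: str
    species_label: str
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float | None
    n_codons: int
    n_discarded: int = 0


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise ValueError(f"saturation: correction undefined for p = {p} >= 0.75")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_dnds(aln: PairwiseCodonAlignment) -> DnDsEstimate:
    """Estimate dN, dS and their ratio for one codon-aligned pair.

    Site totals are averaged over the two sequences; difference counts are
    pathway-averaged per column.  pN = Nd/N, pS = Sd/S are corrected with
    Jukes–Cantor.  Raises on zero usable columns and on saturation
    (pN or pS >= 0.75, where the correction diverges).
    """
    usable = aln.usable_columns()
    if not usable:
        raise ValueError(f"zero usable codon columns for {aln.gene_id}/{aln.species_label}")
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for codon_a, codon_b in usable:
        na, sa = count_sites(codon_a)
        nb, sb = count_sites(codon_b)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = count_differences(codon_a, codon_b)
        nd += d_n
        sd += d_s
    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pN = nd / N if N > 0 else 0.0
    pS = sd / S if S > 0 else 0.0
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    ratio = dN / dS if dS > 0 else None
    return DnDsEstimate(
        gene_id=aln.gene_id,
        species_label=aln.species_label,
        N_sites=N,
        S_sites=S,
        Nd=nd,
        Sd=sd,
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        ratio=ratio,
        n_codons=len(usable),
        n_discarded=len(aln.columns) - len(usable),
    )


@dataclass(frozen=True)
class DIRecord:
    """Per-gene divergence index over the comparator panel."""

    gene_id: str
    pair_ratios: tuple[tuple[str, float | None], ...]
    n_used: int
    di: float | None
    selection_class: str = field(default="undefined")


def classify_selection(
    di: float | None, neutrality_band: tuple[float, float] = DEFAULT_NEUTRALITY_BAND
) -> str:
    """Map a DI value to a selection mode.

    Below the neutrality band: stabilizing selection; within it: evolution
    consistent with neutrality; above: diversifying selection.  The band is
    configurable; the definition gives "DI ≈ 1" no width, so the default
    [0.9, 1.1] is a package choice.
    """
    if di is None:
        return "undefined"
    if di < 0:
        raise ValueError(f"DI must be >= 0, got {di}")
    low, high = neutrality_band
    if not 0 <= low < high:
        raise ValueError(f"invalid neutrality band {neutrality_band}")
    if di < low:
        return "stabilizing"
    if di > high:
        return "diversifying"
    return "neutral"


def compute_di(
    estimates: Iterable[DnDsEstimate] | Mapping[str, float | None],
    gene_id: str | None = None,
    neutrality_band: tuple[float, float] = DEFAULT_NEUTRALITY_BAND,
) -> DIRecord:
    """Aggregate pairwise ratios into a gene's divergence index.

    Accepts either :class:`DnDsEstimate` objects or a mapping
    ``species -> ratio``.  Undefined ratios (dS = 0 pairs) are excluded
    from the mean; with no defined ratio the DI itself is undefined.
    Duplicate comparator species are an error.
    """
    if isinstance(estimates, Mapping):
        pairs: list[tuple[str, float | None]] = list(estimates.items())
    else:
        ests = list(estimates)
        pairs = [(e.species_label, e.ratio) for e in ests]
        gene_ids = {e.gene_id for e in ests}
        if len(gene_ids) > 1:
            raise ValueError(f"estimates span multiple genes: {sorted(gene_ids)}")
        if gene_id is None and gene_ids:
            gene_id = gene_ids.pop()
    species = [s for s, _ in pairs]
    if len(species) != len(set(species)):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(f"duplicate comparator species: {dupes}")
    defined = [r for _, r in pairs if r is not None]
    for r in defined:
        if r < 0:
            raise ValueError(f"negative dN/dS ratio {r}")
    di = sum(defined) / len(defined) if defined else None
    return DIRecord(
        gene_id=gene_id or "",
        pair_ratios=tuple(pairs),
        n_used=len(defined),
        di=di,
        selection_class=classify_selection(di, neutrality_band),
    )
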