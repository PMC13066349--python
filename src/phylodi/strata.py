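"""Taxon ladder and phylostratigraphic age assignment.

A gene's phylostratigraphic age index (PAI) is the rank, on an ordered
ladder of 16 taxonomic stages from the root of the tree of life (rank 1,
cellular organisms) down to the focal species (rank 16, *Homo sapiens*),
of the deepest stage at which an ortholog of the gene is still detectable.
Detection is evidence-based: a gene maps to the minimum rank among species
whose best-hit ortholog is at least ``identity_threshold`` identical to the
focal sequence.  Lower PAI means an evolutionarily older gene.

Identity values are consumed as precomputed fractions (KEGG-SSDB-style
best-hit output); this module never aligns sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "StratumLadder",
    "OrthologHit",
    "AgeDistribution",
    "DEFAULT_LADDER_ROWS",
    "default_ladder",
    "default_species_map",
    "assign_pai",
    "assign_pai_table",
    "age_distribution",
]

# rank, taxon, approximate divergence age (million years ago)
DEFAULT_LADDER_ROWS: tuple[tuple[int, str, float], ...] = (
    (1, "Cellular organisms", 4100.0),
    (2, "Eukaryota", 1850.0),
    (3, "Metazoa", 665.0),
    (4, "Chordata", 541.0),
    (5, "Craniata", 535.0),
    (6, "Vertebrata", 525.0),
    (7, "Euteleostomi", 420.0),
    (8, "Mammalia", 225.0),
    (9, "Eutheria", 160.0),
    (10, "Euarchontoglires", 65.0),
    (11, "Primates", 55.0),
    (12, "Haplorrhini", 50.0),
    (13, "Catarrhini", 44.0),
    (14, "Hominidae", 17.0),
    (15, "Homo", 2.8),
    (16, "Homo sapiens", 0.35),
)

FOCAL_RANK = 16


@dataclass(frozen=True)
class StratumLadder:
    """Ordered ladder of taxonomic stages used to date gene origins.

    ``entries`` is an ordered tuple of ``(rank, taxon_name, age_mya)`` with
    ranks exactly 1..n (n = 16 by default), strictly increasing, and ages
    strictly decreasing (older stages are deeper in the tree).
    """

    entries: tuple[tuple[int, str, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty ladder")
        ranks = [r for r, _, _ in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"ladder ranks must be exactly 1..{len(ranks)}, got {ranks}")
        ages = [a for _, _, a in self.entries]
        if any(a1 <= a2 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("ladder ages must be strictly decreasing with rank")

    @property
    def ranks(self) -> range:
        return range(1, len(self.entries) + 1)

    @property
    def max_rank(self) -> int:
        return len(self.entries)

    def taxon(self, rank: int) -> str:
        return self.entries[rank - 1][1]

    def age_mya(self, rank: int) -> float:
        return self.entries[rank - 1][2]


def default_ladder() -> StratumLadder:
    """The 16-stage human lineage ladder (cellular organisms → H. sapiens)."""
    return StratumLadder(DEFAULT_LADDER_ROWS)


def default_species_map(ladder: StratumLadder | None = None) -> dict[str, int]:
    """A synthetic one-representative-species-per-stage divergence map.

    Each non-focal stage gets a placeholder species label ``sp_r<rank>``
    mapping to the rank at which that species' lineage split from the focal
    lineage; the focal species maps to the terminal rank.  Real analyses
    supply their own map (tab-separated ``species<TAB>rank``).
    """
    ladder = ladder or default_ladder()
    mapping = {f"sp_r{rank:02d}": rank for rank in ladder.ranks if rank != ladder.max_rank}
    mapping["Homo sapiens"] = ladder.max_rank
    return mapping


@dataclass(frozen=True)
class OrthologHit:
    """Best-hit evidence row: gene, subject species, identity fraction."""

    gene_id: str
    species_label: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"identity must be a fraction in [0, 1], got {self.identity!r} "
                f"for {self.gene_id}/{self.species_label}"
            )


def assign_pai(
    hits: Iterable[OrthologHit],
    species_map: Mapping[str, int],
    identity_threshold: float = 0.5,
    ladder: StratumLadder | None = None,
) -> int:
    """Assign the phylostratigraphic age index for one gene.

    Returns the minimum divergence rank among species whose hit identity is
    ``>= identity_threshold`` (the bound is closed: "50 % or more" at the
    default threshold).  A gene with no qualifying hit in any non-focal
    species is assigned the terminal (focal-species) rank: its origin cannot
    be traced deeper than the focal lineage itself.
    """
    ladder = ladder or default_ladder()
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    best = ladder.max_rank
    for hit in hits:
        try:
            rank = species_map[hit.species_label]
        except KeyError:
            raise KeyError(f"unknown species label: {hit.species_label!r}") from None
        if rank not in ladder.ranks:
            raise ValueError(f"species {hit.species_label!r} maps to rank {rank} outside the ladder")
        if hit.identity >= identity_threshold and rank < best:
            best = rank
    return best


def assign_pai_table(
    hits: "pd.DataFrame",
    species_map: Mapping[str, int],
    gene_ids: Iterable[str],
    identity_threshold: float = 0.5,
    ladder: StratumLadder | None = None,
) -> "pd.Series":
    """Vectorised :func:`assign_pai` over a hits table.

    ``hits`` needs columns ``gene_id``, ``species``, ``identity``.  Every
    gene in ``gene_ids`` receives a rank; genes absent from the table (or
    with only sub-threshold hits) get the terminal rank.
    """
    import pandas as pd

    ladder = ladder or default_ladder()
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    gene_ids = list(gene_ids)
    if len(hits):
        unknown = set(hits["species"]) - set(species_map)
        if unknown:
            raise KeyError(f"unknown species label: {sorted(unknown)[0]!r}")
        bad = (hits["identity"] < 0) | (hits["identity"] > 1)
        if bad.any():
            row = hits[bad].iloc[0]
            raise ValueError(
                f"identity must be a fraction in [0, 1], got {row['identity']!r} for {row['gene_id']}"
            )
        kept = hits[hits["identity"] >= identity_threshold]
        ranks = kept["species"].map(species_map)
        minima = ranks.groupby(kept["gene_id"]).min()
    else:
        minima = pd.Series(dtype=int)
    pai = pd.Series(ladder.max_rank, index=pd.Index(gene_ids, name="gene_id"), name="pai")
    common = minima.index.intersection(pai.index)
    pai.loc[common] = minima.loc[common].astype(int)
    return pai


@dataclass(frozen=True)
class AgeDistribution:
    """Counts and percentages of genes per ladder rank."""

    counts: dict[int, int]
    percent: dict[int, float]
    total: int


def age_distribution(pai_values: Iterable[int], ladder: StratumLadder | None = None) -> AgeDistribution:
    """Tabulate a PAI distribution over all ladder ranks.

    Counts sum to the number of inputs and percentages to 100.  Empty input
    is an error: percentages would be undefined.
    """
    ladder = ladder or default_ladder()
    values = list(pai_values)
    if not values:
        raise ValueError("empty input: age distribution undefined")
    out_of_range = [v for v in values if v not in ladder.ranks]
    if out_of_range:
        raise ValueError(f"PAI value {out_of_range[0]} outside ladder ranks 1..{ladder.max_rank}")
    tally = Counter(values)
    counts = {rank: tally.get(rank, 0) for rank in ladder.ranks}
    total = len(values)
    percent = {rank: 100.0 * c / total for rank, c in counts.items()}
    return AgeDistribution(counts=counts, percent=percent, total=total)
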