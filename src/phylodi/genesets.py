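"""Gene universe with annotations, set constructions and keyword filtering.

The analysis operates on a universe of protein-coding genes, each carrying
a phylostratigraphic age index (PAI), a divergence index (DI), binary
functional flags (GPCR membership, brain-specific expression, association
with developmental processes) and free-text GO term names.  Flags derived
from external services (GPCRdb membership, tissue-specific expression) are
consumed as given annotation columns, never computed here.

Gene sets are built by ordinary set algebra (e.g. the appetite-regulating
GPCRs are the intersection of the receptor set with the GPCR superfamily
set) and by a case-insensitive keyword filter over GO term names (the
development/growth/morphogenesis filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "GeneSet",
    "DEVELOPMENT_KEYWORDS",
    "intersect",
    "difference",
    "development_filter",
]

DEVELOPMENT_KEYWORDS: tuple[str, ...] = ("development", "growth", "morphogenesis")


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its evolutionary indices and functional annotations.

    ``pai`` is a ladder rank (1..16) or ``None``; ``di`` a nonnegative
    number or ``None``.  Missing values are allowed and are excluded from
    distribution and enrichment denominators downstream.
    """

    gene_id: str
    pai: int | None = None
    di: float | None = None
    is_gpcr: bool = False
    is_brain_specific: bool = False
    is_development: bool = False
    ligand_type: str | None = None
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.di is not None and self.di < 0:
            raise ValueError(f"DI must be >= 0, got {self.di} for {self.gene_id}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids drawn from one universe."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(ids))


def intersect(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Standard set intersection, e.g. receptors ∩ GPCR superfamily."""
    return GeneSet(name=name or f"{a.name}&{b.name}", members=a.members & b.members)


def difference(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Members of ``a`` not in ``b``, e.g. receptors that are not GPCRs."""
    return GeneSet(name=name or f"{a.name}-{b.name}", members=a.members - b.members)


def matches_keywords(go_terms: Sequence[str], keywords: Sequence[str]) -> bool:
    """True if any term name contains any keyword, case-insensitively.

    Plain substring matching, so "developmental" matches "development".
    """
    lowered = [k.lower() for k in keywords]
    return any(any(k in term.lower() for k in lowered) for term in go_terms)


def development_filter(
    universe: Iterable[GeneRecord],
    keywords: Sequence[str] = DEVELOPMENT_KEYWORDS,
    name: str = "development",
) -> GeneSet:
    """Select genes annotated with GO terms containing any keyword.

    The default keywords reproduce the development/growth/morphogenesis
    screen applied to GOTERM_BP_DIRECT term names.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    members = frozenset(
        g.gene_id for g in universe if matches_keywords(g.go_terms, keywords)
    )
    return GeneSet(name=name, members=members)


def check_universe(records: Sequence[GeneRecord]) -> None:
    """Validate a universe: unique gene ids; dev flag consistent with terms.

    Consistency is only enforced for genes that carry GO terms — a gene
    flagged as development-associated without terms is accepted (the flag
    may come from an annotation source not shipped with the table).
    """
    seen: set[str] = set()
    for g in records:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id: {g.gene_id}")
        seen.add(g.gene_id)
        if g.go_terms:
            expected = matches_keywords(g.go_terms, DEVELOPMENT_KEYWORDS)
            if g.is_development != expected:
                raise ValueError(
                    f"is_development flag inconsistent with GO terms for {g.gene_id}"
                )
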