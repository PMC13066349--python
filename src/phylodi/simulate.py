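"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators live here:

* a stochastic universe generator (:func:`generate_universe`) that samples
  gene records — phylostratigraphic ages from a 16-category distribution,
  divergence indices from a mixture over [0, ∞), binary flags with
  controllable enrichment odds — together with ortholog-hit tables
  constructed so that age assignment recovers every planted age exactly;

* a codon-pair simulator (:func:`simulate_codon_pair`) that evolves a
  derived sequence away from a uniformly drawn ancestor until a target
  synonymous divergence is reached, accepting nonsynonymous proposals
  with probability proportional to omega, for validating the dN/dS
  estimator by parameter recovery;

plus :func:`generate_paperlike_fixture`, a fully deterministic universe of
19,504 genes containing the nested study sets (420 GPCRs, 80 receptors,
67 = 80 ∩ 420, 13 = 80 \\ 420, 23 development-associated) with planted
category counts, so that the downstream enrichment report is reproducible
byte for byte.  The fixture is synthetic: gene ids are generated labels,
not curated gene symbols.

All stochastic operations take explicit seeds and use numpy's PCG64
generator, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .divergence import _AA, SENSE_CODONS, STOP_CODONS, PairwiseCodonAlignment
from .genesets import GeneSet
from .strata import StratumLadder, default_ladder, default_species_map

__all__ = [
    "DiComponent",
    "FlagSpec",
    "UniverseSpec",
    "CodonSimSpec",
    "PaperLikeFixture",
    "default_pai_probabilities",
    "default_di_mixture",
    "generate_universe",
    "simulate_codon_pair",
    "generate_paperlike_fixture",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# universe specification


@dataclass(frozen=True)
class DiComponent:
    """One mixture component for divergence-index values.

    ``kind`` is "lognormal" (params mu, sigma of log DI) or "point"
    (params value).
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mean=mu, sigma=sigma, size=size)
        if self.kind == "point":
            return np.full(size, self.params[0])
        raise ValueError(f"unknown DI component kind: {self.kind!r}")


@dataclass(frozen=True)
class FlagSpec:
    """A binary flag with a base rate and enrichment odds vs. a predicate.

    ``odds`` is the odds ratio of the flag between genes satisfying
    ``condition`` and the rest; the marginal rate stays at ``base_rate``.
    ``condition`` maps (pai, di) -> bool; with no condition the flag is
    i.i.d. Bernoulli(base_rate).
    """

    base_rate: float
    odds: float = 1.0
    condition: Callable[[int, float], bool] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError(f"base_rate must be in [0, 1], got {self.base_rate}")
        if self.odds <= 0:
            raise ValueError(f"odds must be > 0, got {self.odds}")


def _split_rates(base_rate: float, odds: float, f_cond: float) -> tuple[float, float]:
    """Per-group rates (p_true, p_false) with the given odds ratio and margin."""
    if odds == 1.0 or f_cond in (0.0, 1.0) or base_rate in (0.0, 1.0):
        return base_rate, base_rate

    def margin(p0: float) -> float:
        o0 = p0 / (1 - p0)
        p1 = odds * o0 / (1 + odds * o0)
        return f_cond * p1 + (1 - f_cond) * p0 - base_rate

    p0 = brentq(margin, 1e-12, 1 - 1e-12)
    o0 = p0 / (1 - p0)
    p1 = odds * o0 / (1 + odds * o0)
    return p1, p0


def default_pai_probabilities() -> np.ndarray:
    """Default 16-category age distribution for sampled universes.

    Shaped after the genome-wide picture the analysis assumes: about a
    third of genes at the root stage, local modes at the vertebrate and
    bony-vertebrate stages (~16 % and ~14 %), very few at stages 4–5, and
    a thin tail toward the focal species.
    """
    counts = np.array(
        [6350, 1500, 2000, 150, 155, 3203, 2708, 735, 900, 500, 400, 300, 250, 180, 100, 73],
        dtype=float,
    )
    return counts / counts.sum()


def default_di_mixture() -> tuple[tuple[float, DiComponent], ...]:
    """Default DI distribution: one lognormal calibrated to the genome-wide
    shares (44.7 % of genes at DI <= 0.25 and 5.85 % above 1).

    Solving P(ln X <= ln 0.25) = 0.447 and P(ln X > 0) = 0.0585 gives
    mu = -1.2778, sigma = 0.8148.
    """
    return ((1.0, DiComponent("lognormal", (-1.2778, 0.8148))),)


@dataclass(frozen=True)
class UniverseSpec:
    """Specification for a sampled gene universe."""

    n_genes: int
    pai_probabilities: Sequence[float] = field(default_factory=default_pai_probabilities)
    di_mixture: Sequence[tuple[float, DiComponent]] = field(default_factory=default_di_mixture)
    flag_specs: dict[str, FlagSpec] = field(
        default_factory=lambda: {
            "is_gpcr": FlagSpec(base_rate=0.0215),
            "is_brain_specific": FlagSpec(base_rate=0.05),
            "is_development": FlagSpec(
                base_rate=0.2, odds=4.0, condition=lambda pai, di: di <= 0.25
            ),
        }
    )
    seed: int = 0
    identity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be > 0, got {self.n_genes}")
        probs = np.asarray(self.pai_probabilities, dtype=float)
        if probs.shape != (16,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("pai_probabilities must be a 16-vector of nonnegative values summing to 1")
        weights = [w for w, _ in self.di_mixture]
        if not weights or abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("di_mixture weights must be nonnegative and sum to 1")


def _hits_for_gene(
    gene_id: str,
    pai: int,
    rng: np.random.Generator,
    species_by_rank: dict[int, str],
    threshold: float,
    max_rank: int,
) -> list[tuple[str, str, float]]:
    """Hit rows guaranteeing exact age recovery for one planted age.

    Ranks at or above the planted age get above-threshold identities
    (deeper-rank species, being closer to the focal lineage, would also
    carry detectable orthologs); any decoy hit below the planted age is
    strictly sub-threshold.
    """
    rows: list[tuple[str, str, float]] = []
    if pai < max_rank:
        # the defining hit at the planted rank
        rows.append((gene_id, species_by_rank[pai], float(threshold + (1 - threshold) * rng.random())))
        # extra qualifying hits at younger (higher-rank) stages
        for rank in range(pai + 1, max_rank):
            if rng.random() < 0.5:
                rows.append(
                    (gene_id, species_by_rank[rank], float(threshold + (1 - threshold) * rng.random()))
                )
    # sub-threshold decoys at older stages never change the assignment
    for rank in range(1, pai):
        if rng.random() < 0.15:
            rows.append((gene_id, species_by_rank[rank], float(threshold * rng.random() * 0.999)))
    return rows


def generate_universe(
    spec: UniverseSpec, ladder: StratumLadder | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a gene universe and matching ortholog-hit table.

    Returns ``(universe, hits)`` DataFrames.  The hit table is constructed
    so age assignment at ``spec.identity_threshold`` recovers the planted
    age of every gene exactly; flags are drawn with the configured
    enrichment odds while keeping their marginal base rates.
    """
    ladder = ladder or default_ladder()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    pai = rng.choice(np.arange(1, 17), size=n, p=np.asarray(spec.pai_probabilities, dtype=float))

    weights = np.array([w for w, _ in spec.di_mixture])
    comp_idx = rng.choice(len(weights), size=n, p=weights)
    di = np.empty(n)
    for k, (_, comp) in enumerate(spec.di_mixture):
        mask = comp_idx == k
        di[mask] = comp.sample(rng, int(mask.sum()))

    flags: dict[str, np.ndarray] = {}
    for name, fs in spec.flag_specs.items():
        if fs.condition is None:
            flags[name] = rng.random(n) < fs.base_rate
        else:
            cond = np.array([bool(fs.condition(int(p), float(d))) for p, d in zip(pai, di)])
            p1, p0 = _split_rates(fs.base_rate, fs.odds, float(cond.mean()))
            draw = rng.random(n)
            flags[name] = np.where(cond, draw < p1, draw < p0)

    species_map = default_species_map(ladder)
    species_by_rank = {rank: label for label, rank in species_map.items() if rank != ladder.max_rank}
    hit_rows: list[tuple[str, str, float]] = []
    for gid, p in zip(gene_ids, pai):
        hit_rows.extend(
            _hits_for_gene(gid, int(p), rng, species_by_rank, spec.identity_threshold, ladder.max_rank)
        )

    universe = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "pai": pai.astype(int),
            "di": di,
            "is_gpcr": flags.get("is_gpcr", np.zeros(n, bool)),
            "is_brain_specific": flags.get("is_brain_specific", np.zeros(n, bool)),
            "is_development": flags.get("is_development", np.zeros(n, bool)),
            "ligand_type": ["" for _ in range(n)],
            "go_terms": ["" for _ in range(n)],
        }
    )
    hits = pd.DataFrame(hit_rows, columns=["gene_id", "species", "identity"])
    return universe, hits


# ---------------------------------------------------------------------------
# codon-pair simulation


@dataclass(frozen=True)
class CodonSimSpec:
    """Specification for one simulated codon-aligned pair.

    ``omega`` scales the acceptance probability of nonsynonymous proposals
    relative to synonymous ones; ``target_dS`` is the synonymous divergence
    (Jukes–Cantor scale) at which substitution stops; ``ts_tv_ratio``
    weights transition proposals against each transversion.
    """

    n_codons: int
    omega: float = 1.0
    target_dS: float = 0.08
    ts_tv_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons <= 0:
            raise ValueError(f"n_codons must be > 0, got {self.n_codons}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.target_dS < 0:
            raise ValueError(f"target_dS must be >= 0, got {self.target_dS}")
        if self.ts_tv_ratio <= 0:
            raise ValueError(f"ts_tv_ratio must be > 0, got {self.ts_tv_ratio}")


def simulate_codon_pair(
    spec: CodonSimSpec, gene_id: str = "sim", species_label: str = "sim_ortholog"
) -> PairwiseCodonAlignment:
    """Evolve a derived CDS away from a random ancestor.

    The ancestor is drawn uniformly over sense codons.  Single-nucleotide
    proposals (uniform position; alternative base weighted by the ts/tv
    ratio) are rejected if they create a stop codon; synonymous proposals
    are accepted with probability min(1, 1/omega) and nonsynonymous ones
    with probability min(1, omega), i.e. proportional to omega.
    Substitution stops once the number of accepted synonymous changes
    reaches the count implied by ``target_dS`` on the ancestor's
    synonymous sites.
    """
    from .divergence import count_sites

    rng = np.random.default_rng(spec.seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=spec.n_codons)]
    ancestor = list(codons)
    derived = list(codons)

    if spec.target_dS == 0:
        cols = tuple(zip(ancestor, derived))
        return PairwiseCodonAlignment(gene_id, species_label, cols)

    s_sites = sum(count_sites(c)[1] for c in ancestor)
    p_s_target = 0.75 * (1.0 - math.exp(-4.0 * spec.target_dS / 3.0))
    target_syn = max(1, round(p_s_target * s_sites))

    scale = max(1.0, spec.omega)
    p_syn = 1.0 / scale
    p_non = spec.omega / scale
    kappa = spec.ts_tv_ratio

    syn_fixed = 0
    guard = 0
    max_proposals = 500_000 + 200 * target_syn
    while syn_fixed < target_syn:
        guard += 1
        if guard > max_proposals:
            raise RuntimeError(
                f"simulation failed to reach target synonymous divergence "
                f"({syn_fixed}/{target_syn} after {guard} proposals)"
            )
        idx = int(rng.integers(spec.n_codons))
        pos = int(rng.integers(3))
        codon = derived[idx]
        old = codon[pos]
        alternatives = [b for b in _BASES if b != old]
        if kappa == 1.0:
            new = alternatives[int(rng.integers(3))]
        else:
            w = np.array([kappa if b == _TRANSITION[old] else 1.0 for b in alternatives])
            new = alternatives[int(rng.choice(3, p=w / w.sum()))]
        candidate = codon[:pos] + new + codon[pos + 1 :]
        if candidate in STOP_CODONS:
            continue
        synonymous = _AA[candidate] == _AA[codon]
        accept_p = p_syn if synonymous else p_non
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        derived[idx] = candidate
        if synonymous:
            syn_fixed += 1

    cols = tuple(zip(ancestor, derived))
    return PairwiseCodonAlignment(gene_id, species_label, cols)


# ---------------------------------------------------------------------------
# deterministic paper-like fixture


@dataclass(frozen=True)
class PaperLikeFixture:
    """A deterministic synthetic universe with planted category counts."""

    universe: pd.DataFrame
    hits: pd.DataFrame
    sets: dict[str, GeneSet]
    species_map: dict[str, int]
    ladder: StratumLadder


# planted global age counts (rank -> count), summing to 19,504
_FIXTURE_PAI_TOTALS = {
    1: 6350, 2: 1500, 3: 2000, 4: 150, 5: 155, 6: 3203, 7: 2708, 8: 735,
    9: 900, 10: 500, 11: 400, 12: 300, 13: 250, 14: 180, 15: 100, 16: 73,
}

_DEV_TERMS = (
    "positive regulation of neuron growth",
    "embryonic organ development",
    "tissue morphogenesis",
)
_NON_DEV_TERMS = ("ion transport", "signal transduction", "cell adhesion")


def _expand(pairs: Sequence[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


def generate_paperlike_fixture() -> PaperLikeFixture:
    """Deterministic universe of 19,504 genes with the planted structure.

    Planted, exactly (not sampled):

    * nested sets of sizes 420, 80, 67, 13 and a 23-gene development set;
    * age counts: 3,203 genes at rank 6 genome-wide, 152 of the 420 GPCRs
      at rank 6, 37 of the 80 receptors at rank 6 (35 of them GPCRs),
      6 of the 13 non-GPCR receptors at ranks 7–8, 3,443 genes at ranks
      7–8 genome-wide;
    * divergence classes: 8,719 of 19,504 at DI <= 0.25 (44.7 %), 45 of 80
      (38 of 67; 7 of 13), 174 of 420; three receptor genes above 1
      (1.84, 1.21, 1.03) and 1,141 genome-wide;
    * the 23 development genes split 18 (DI <= 0.25) vs 5 across the DI
      partition of the 80-gene set.

    Ortholog hits are laid out so age assignment at threshold 0.5 recovers
    every planted age, including identity values exactly at the bound.
    """
    n_total = 19504
    ladder = default_ladder()
    species_map = default_species_map(ladder)
    species_by_rank = {rank: label for label, rank in species_map.items() if rank != 16}

    # --- membership by index -------------------------------------------------
    # 0..66   appetite GPCRs (in 80 and 420)
    # 67..79  appetite non-GPCR receptors (in 80 only)
    # 80..432 other GPCRs (in 420 only)
    # 433..   background genes
    app_gpcr = list(range(67))
    app_non_gpcr = list(range(67, 80))
    other_gpcr = list(range(80, 433))
    receptors = app_gpcr + app_non_gpcr

    # --- planted ages ---------------------------------------------------------
    pai = np.zeros(n_total, dtype=int)
    pai[app_gpcr] = _expand([(6, 35), (1, 9), (2, 5), (3, 4), (7, 9), (8, 5)])
    pai[app_non_gpcr] = _expand([(6, 2), (7, 4), (8, 2), (1, 2), (2, 1), (3, 1), (9, 1)])
    pai[other_gpcr] = _expand([(6, 117), (1, 80), (2, 30), (3, 40), (7, 50), (8, 10), (9, 26)])

    assigned = pd.Series(pai[:433]).value_counts().to_dict()
    remaining: list[int] = []
    for rank in range(1, 17):
        remaining.extend([rank] * (_FIXTURE_PAI_TOTALS[rank] - assigned.get(rank, 0)))
    if len(remaining) != n_total - 433:
        raise AssertionError("fixture age quota mismatch")
    pai[433:] = remaining

    # --- planted divergence indices ------------------------------------------
    di = np.zeros(n_total)

    def low_values(count: int, start: float = 0.06, stop: float = 0.25) -> np.ndarray:
        return np.round(np.linspace(start, stop, count), 4)

    def mid_values(count: int) -> np.ndarray:
        return np.round(np.linspace(0.27, 0.98, count), 4)

    # appetite GPCRs: 38 low (10 of them < 0.05), 3 high, 26 mid
    di[app_gpcr[:10]] = np.round(np.linspace(0.004, 0.049, 10), 4)
    di[app_gpcr[10:38]] = low_values(28)
    di[app_gpcr[38:41]] = [1.84, 1.21, 1.03]
    di[app_gpcr[41:]] = mid_values(26)
    # non-GPCR receptors: 7 low (1 of them < 0.05), 6 mid
    di[app_non_gpcr[:1]] = [0.045]
    di[app_non_gpcr[1:7]] = low_values(6)
    di[app_non_gpcr[7:]] = mid_values(6)
    # other GPCRs: 136 low, 20 high, 197 mid
    di[other_gpcr[:136]] = low_values(136, start=0.02)
    di[other_gpcr[136:156]] = np.round(np.linspace(1.15, 2.1, 20), 4)
    di[other_gpcr[156:]] = mid_values(197)
    # background: fill remaining class quotas
    n_low_rest = 8719 - 45 - 136
    n_high_rest = 1141 - 3 - 20
    n_bg = n_total - 433
    n_mid_rest = n_bg - n_low_rest - n_high_rest
    bg = slice(433, n_total)
    di[433 : 433 + n_low_rest] = low_values(n_low_rest, start=0.005)
    di[433 + n_low_rest : 433 + n_low_rest + n_high_rest] = np.round(
        np.linspace(1.02, 3.0, n_high_rest), 4
    )
    di[433 + n_low_rest + n_high_rest :] = np.round(
        np.linspace(0.2501, 1.0, n_mid_rest), 4
    )

    # --- development flags within the 80-gene set -----------------------------
    # 18 development genes among the 45 receptors with DI <= 0.25, 5 among the 35 others
    rec_low = [i for i in receptors if di[i] <= 0.25]
    rec_high = [i for i in receptors if di[i] > 0.25]
    if (len(rec_low), len(rec_high)) != (45, 35):
        raise AssertionError("fixture DI partition of the receptor set mismatch")
    dev_idx = set(rec_low[:18]) | set(rec_high[:5])
    is_dev = np.zeros(n_total, dtype=bool)
    is_dev[list(dev_idx)] = True

    # brain-specificity: 15 of the 80 receptors, sparse elsewhere
    is_brain = np.zeros(n_total, dtype=bool)
    is_brain[receptors[:15]] = True
    is_brain[500:n_total:400] = True

    is_gpcr = np.zeros(n_total, dtype=bool)
    is_gpcr[app_gpcr] = True
    is_gpcr[other_gpcr] = True

    ligand = np.array([""] * n_total, dtype=object)
    ligand[receptors] = _expand_ligands()

    go_terms = np.array([""] * n_total, dtype=object)
    for k, i in enumerate(sorted(dev_idx)):
        go_terms[i] = ";".join((_DEV_TERMS[k % len(_DEV_TERMS)], _NON_DEV_TERMS[k % 3]))
    for k, i in enumerate(sorted(set(receptors) - dev_idx)):
        go_terms[i] = _NON_DEV_TERMS[k % 3]

    gene_ids = [f"g{i:05d}" for i in range(n_total)]
    universe = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "pai": pai,
            "di": np.round(di, 4),
            "is_gpcr": is_gpcr,
            "is_brain_specific": is_brain,
            "is_development": is_dev,
            "ligand_type": ligand,
            "go_terms": go_terms,
        }
    )

    # --- ortholog hits recovering the planted ages, deterministically ---------
    rows: list[tuple[str, str, float]] = []
    for i, (gid, rank) in enumerate(zip(gene_ids, pai)):
        rank = int(rank)
        if rank < 16:
            # defining hit; every third gene sits exactly at the closed bound
            identity = 0.5 if i % 3 == 0 else round(0.55 + (i % 40) * 0.01, 4)
            rows.append((gid, species_by_rank[rank], identity))
            if rank + 1 < 16 and i % 2 == 0:  # extra qualifying hit at a younger stage
                rows.append((gid, species_by_rank[rank + 1], round(0.6 + (i % 35) * 0.01, 4)))
        if rank > 1 and i % 4 == 0:  # sub-threshold decoy at an older stage
            rows.append((gid, species_by_rank[max(1, rank - 2)], round(0.05 + (i % 45) * 0.01, 4)))
    hits = pd.DataFrame(rows, columns=["gene_id", "species", "identity"])

    ids = np.array(gene_ids)
    sets = {
        "Receptors_80": GeneSet.from_ids("Receptors_80", ids[receptors]),
        "allGPCR_420": GeneSet.from_ids("allGPCR_420", ids[app_gpcr + other_gpcr]),
        "allCDS_19504": GeneSet.from_ids("allCDS_19504", ids),
    }
    return PaperLikeFixture(
        universe=universe, hits=hits, sets=sets, species_map=species_map, ladder=ladder
    )


def _expand_ligands() -> list[str]:
    # 45 peptide / 11 protein / 8 lipid / 7 aminergic / 1 other / 8 orphan
    return _expand_str(
        [("peptide", 45), ("protein", 11), ("lipid", 8), ("aminergic", 7), ("other", 1), ("orphan", 8)]
    )


def _expand_str(pairs: Sequence[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in pairs:
        out.extend([value] * count)
    return out
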