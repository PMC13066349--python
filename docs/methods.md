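# Methods

`phylodi` implements an evolutionary characterization pipeline for human
gene sets built around two per-gene indices — a phylostratigraphic age
index (PAI) and a divergence index (DI) — and an observed-vs-expected
enrichment analysis over partitions of a study set against background
gene sets. This note records the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical choices at the edges.

## Phylostratigraphic age (PAI)

A gene's age is the rank, on an ordered 16-stage ladder from the root of
the tree of life (rank 1, cellular organisms, ~4,100 Mya) to the focal
species (rank 16, *Homo sapiens*, ~0.35 Mya), of the deepest stage at
which an ortholog of the gene is detectable. Detection is evidence-based:
the input is a best-hit table (gene, subject species, identity fraction,
KEGG-SSDB-style), and a hit counts iff its identity is **at or above**
the threshold (default 0.5 — "50 % or more", a closed bound). The gene's
PAI is the minimum divergence rank among qualifying species; a gene with
no qualifying hit outside the focal species gets rank 16, because its
origin cannot be traced deeper than the focal lineage. Lower PAI = older
gene.

Choices worth noting:

* The species → divergence-rank map is supplied as data, not inferred
  from a taxonomy service; the module never performs homology searches.
* Identity is consumed as a precomputed fraction. Whether identity was
  computed on protein or DNA sequences is an upstream decision this
  module is agnostic to; the two conventions can disagree, so the input's
  provenance should be stated alongside any result.
* No correction for homology-detection failure is attempted: a fast-
  evolving gene whose deep orthologs fall below the identity threshold
  will look younger than it is. This is a known bias of threshold-based
  phylostratigraphy, inherited by design.

## Divergence index (DI) and dN/dS

DI is the arithmetic mean of pairwise dN/dS ratios between the focal
coding sequence and its orthologs in four hominids (chimpanzee, bonobo,
western lowland gorilla, Sumatran orangutan — a configurable panel):

    DI = (1/n) Σᵢ (dN/dS)ᵢ

DI ≪ 1 indicates strong stabilizing (purifying) selection, DI ≈ 1
neutrality, DI > 1 diversifying selection.

The pairwise estimator is Nei–Gojobori (1986) counting with Jukes–Cantor
correction. It was chosen because it is deterministic, closed-form and
exhaustively testable against brute-force enumeration; it sits behind a
small interface so a codon-ML estimator could be added without touching
the DI aggregation. Details:

* **Site counting.** Per codon position, the synonymous fraction is the
  number of single-nucleotide changes to a sense codon for the same amino
  acid divided by the number of changes to any sense codon (mutations to
  stops are excluded from the denominator). Fractions sum to exactly 3
  per codon; pair totals average the two sequences.
* **Difference counting.** Between two codons, counts are averaged over
  all orderings of the differing positions; orderings passing through a
  stop codon are excluded, and if every ordering is excluded the average
  falls back to all orderings with stop-touching steps counted as
  nonsynonymous. nd + sd always equals the codon Hamming distance.
* **Correction.** d = −(3/4)·ln(1 − 4p/3) applied to pN = Nd/N and
  pS = Sd/S. p ≥ 0.75 is a hard error ("saturation") rather than a
  clamped value — at hominid divergences it indicates a data problem.
* **dS = 0 pairs.** Common between hominids. The pair's ratio is
  undefined (no 0/0 fabrication) and excluded from the DI mean; n_used
  records how many pairs contributed. A gene whose pairs are all
  undefined has missing DI and is excluded from DI-based denominators
  downstream, with the exclusion logged.
* **Gapped/ambiguous columns** are discarded before counting and the
  count is logged per alignment.
* **Classification.** The neutrality band has no canonical width; the
  default band [0.9, 1.1] (inclusive) separates "stabilizing" /
  "neutral" / "diversifying" and is configurable. Every gene discussed in
  the analyses this package supports falls far outside any reasonable
  band, so the default is not load-bearing.

## Enrichment statistics

For a study set of n genes and a background of size M with m genes in a
category, the expected study count is n·m/M (reported at two decimals;
full precision internally). Observed vs expected is tested with a
two-cell 1-df chi-square goodness of fit without continuity correction:

    χ² = (obs − exp)²/exp + ((n−obs) − (n−exp))²/(n−exp)

The 2×2 variant (DI partition × development association) takes expected
cells from the margins under independence, sums (obs−exp)²/exp over four
cells, df = 1, again without Yates correction. This construction — and
not, say, a corrected or multi-df variant — is the one that lands every
printed comparison in its printed significance tier, which is why it is
the default and the only implemented form. p-values are reported exactly
and as the smallest conventional tier exceeded (p < 0.001 / 0.01 / 0.05).
No multiple-testing correction is applied, matching the analysis design
this package reproduces; users running many categories should apply
their own.

An exact binomial upper tail is provided for "k of n genes share a
category" questions. The null proportion for such clustering statements
is a modelling choice the caller must make (e.g. the genome-wide category
fraction); nothing in the package asserts one.

Displayed percentages round half-up (56.25 % → 56.3 %); expected counts
use banker's rounding, which matches how the reference values were
printed (10.0625 → 10.06).

## Synthetic data

The generator exists so every stage runs and is validated without
external downloads; no accession-level data ships with the package.

**Sampled universes** (`generate_universe`) draw PAI from a 16-category
distribution (default shaped like the genome-wide picture: ~33 % at rank
1, ~16 % at rank 6, ~14 % at rank 7, ~1.6 % at ranks 4–5), DI from a
mixture over [0, ∞) (default a single lognormal with μ = −1.2778,
σ = 0.8148, solved so that P(DI ≤ 0.25) = 0.447 and P(DI > 1) = 0.0585),
and binary flags with controllable enrichment odds at a fixed marginal
rate (per-group rates solved from the odds ratio and the margin). Hit
tables are constructed so that age assignment recovers every planted age
exactly: a qualifying hit at the planted rank, optional qualifying hits
at younger ranks, and only sub-threshold decoys at older ranks.

**The deterministic study fixture** (`generate_paperlike_fixture`)
plants — not samples — a 19,504-gene universe with nested sets of sizes
420 / 80 / 67 / 13 / 23 and exact category counts (3,203 genes at rank 6;
152 of 420; 37 of 80; 3,443 at ranks 7–8 with 6 of 13; 8,719 at
DI ≤ 0.25 with 45 of 80, 38 of 67 and 174 of 420; the 18/5 development
split across the DI partition; 1,141 genes with DI > 1, including study
genes at 1.84, 1.21, 1.03). Counts the reference analysis reports only as
rounded percentages (44.7 % of genes at DI ≤ 0.25; the 27.8 expected
count) fix the planted integers to 8,719/19,504 and 174/420. Exact
DI values within a class are arbitrary evenly spaced grids; only class
membership matters downstream. Gene ids are synthetic labels.

**The codon simulator** (`simulate_codon_pair`) draws an ancestor
uniformly over the 61 sense codons and applies single-nucleotide
proposals (uniform position; alternative base weighted by a ts/tv ratio,
default 1), rejecting stops, accepting synonymous changes with
probability min(1, 1/ω) and nonsynonymous with min(1, ω), until the
accepted synonymous changes reach the count implied by the target dS on
the ancestor's synonymous sites. With the default uniform proposal
kernel the NG86 estimator is unbiased at ω = 1; a ts/tv ratio ≠ 1
introduces the well-known NG86 bias and is supported for exactly that
kind of sensitivity exercise, not used by default. Validation uses
3,000-codon pairs at dS ≈ 0.08 with 50 replicate seeds per ω (25 in the
analysis driver) — sizes at which sampling error on the mean ratio is a
few percent. Multiple hits at one site can revert earlier changes, so
realized divergence can drift slightly below the target; at dS ≈ 0.08
the effect is negligible.

What the synthetic data does **not** emulate: real codon usage and
composition, indels, rate variation across sites and genes, correlated
annotation structure (GO term co-occurrence), paralogy confusion in hit
tables, or identity values derived from actual alignments. Passing tests
therefore demonstrate correctness of the computations and internal
consistency of the pipeline, not robustness to the messiness of real
orthology data.

## Pipeline and determinism

`run_pipeline` executes: age assignment from hits → (optional) dN/dS and
DI estimation from codon alignments, otherwise the universe's DI column
is taken as given → set constructions (intersection, difference,
development-keyword filter: case-insensitive substring match of GO term
names against {development, growth, morphogenesis}) → distributions →
enrichment tests → the 2×2 development test. Every filtering decision is
logged: genes without hits, missing PAI/DI excluded from denominators,
dS = 0 pairs, discarded alignment columns, degenerate comparisons
skipped.

All randomness flows through explicit seeds into numpy's PCG64
generator; report writers emit no timestamps, so identical inputs and
configuration give byte-identical outputs. The deterministic fixture
plus pipeline run takes well under a second.

## Known limitations

* The dN/dS estimator is counting-based; for divergences far beyond the
  hominid range, or strong codon-usage bias, a likelihood estimator
  would be preferable.
* PAI inherits every bias of threshold-based ortholog detection.
* The enrichment tests treat genes as independent draws; gene-family
  structure violates this in real data.
* The development filter matches term names only, not definitions, and
  any term containing a keyword substring counts ("growth cone
  collapse" would match "growth").
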