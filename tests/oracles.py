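"""Independent brute-force oracles used by the test suite.

These re-derive synonymous/nonsynonymous site fractions and pathway-
averaged difference counts by direct enumeration over the standard
genetic code, sharing no code with the package's estimator, so that
agreement is a real cross-check rather than a tautology.
"""

from itertools import permutations, product

from Bio.Seq import Seq

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in product(BASES, repeat=3)]


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


SENSE = [c for c in ALL_CODONS if translate(c) != "*"]


def site_fractions(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site fractions by neighbour enumeration."""
    aa = translate(codon)
    syn_total = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + base + codon[pos + 1 :]
            for base in BASES
            if base != codon[pos]
        ]
        sense_neighbours = [n for n in neighbours if translate(n) != "*"]
        if sense_neighbours:
            syn = sum(1 for n in sense_neighbours if translate(n) == aa)
            syn_total += syn / len(sense_neighbours)
    return 3.0 - syn_total, syn_total


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) difference counts by pathway enumeration.

    Enumerates every ordering of the differing positions, drops orderings
    whose intermediate states are stop codons, classifies each step by
    translation, and averages.  If all orderings are dropped, averages
    over all of them, counting steps touching a stop as nonsynonymous.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    valid, fallback = [], []
    for order in permutations(diffs):
        steps = []
        state = codon_a
        through_stop = False
        for pos in order:
            nxt = state[:pos] + codon_b[pos] + state[pos + 1 :]
            if translate(nxt) == "*":
                through_stop = True
            steps.append((state, nxt))
            state = nxt
        nd = sd = 0.0
        for s, t in steps:
            if translate(s) != "*" and translate(t) != "*" and translate(s) == translate(t):
                sd += 1.0
            else:
                nd += 1.0
        fallback.append((nd, sd))
        if not through_stop:
            valid.append((nd, sd))
    pool = valid or fallback
    nd = sum(x for x, _ in pool) / len(pool)
    sd = sum(y for _, y in pool) / len(pool)
    return nd, sd
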