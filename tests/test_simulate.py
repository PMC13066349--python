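"""Synthetic universe generator, codon simulator and the planted fixture."""

import numpy as np
import pandas as pd
import pytest

from phylodi.divergence import _AA, estimate_dnds
from phylodi.simulate import (
    CodonSimSpec,
    DiComponent,
    UniverseSpec,
    generate_universe,
    simulate_codon_pair,
)
from phylodi.strata import assign_pai_table, default_species_map


class TestGenerateUniverse:
    def test_same_seed_is_identical(self):
        spec = UniverseSpec(n_genes=200, seed=42)
        u1, h1 = generate_universe(spec)
        u2, h2 = generate_universe(spec)
        pd.testing.assert_frame_equal(u1, u2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_different_seed_differs(self):
        u1, _ = generate_universe(UniverseSpec(n_genes=200, seed=1))
        u2, _ = generate_universe(UniverseSpec(n_genes=200, seed=2))
        assert not u1["pai"].equals(u2["pai"])

    def test_degenerate_age_distribution(self):
        probs = np.zeros(16)
        probs[5] = 1.0  # all mass at rank 6
        universe, hits = generate_universe(UniverseSpec(n_genes=300, pai_probabilities=probs, seed=0))
        recovered = assign_pai_table(hits, default_species_map(), universe["gene_id"])
        assert (recovered == 6).mean() >= 0.99

    def test_planted_ages_recovered_exactly(self):
        universe, hits = generate_universe(UniverseSpec(n_genes=500, seed=7))
        recovered = assign_pai_table(hits, default_species_map(), universe["gene_id"])
        assert (recovered.loc[universe["gene_id"]].values == universe["pai"].values).all()

    def test_flag_enrichment_direction(self):
        universe, _ = generate_universe(UniverseSpec(n_genes=4000, seed=3))
        low = universe["di"] <= 0.25
        rate_low = universe.loc[low, "is_development"].mean()
        rate_high = universe.loc[~low, "is_development"].mean()
        assert rate_low > rate_high  # planted odds ratio of 4 shows through
        assert universe["is_development"].mean() == pytest.approx(0.2, abs=0.03)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="pai_probabilities"):
            UniverseSpec(n_genes=10, pai_probabilities=np.full(16, 0.1))

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            UniverseSpec(n_genes=10, di_mixture=((0.5, DiComponent("point", (0.1,))),))


class TestSimulateCodonPair:
    def test_omega_zero_all_fixed_differences_synonymous(self):
        aln = simulate_codon_pair(CodonSimSpec(n_codons=500, omega=0.0, target_dS=0.05, seed=1))
        for a, b in aln.columns:
            if a != b:
                assert _AA[a] == _AA[b]
        assert estimate_dnds(aln).ratio == 0.0

    def test_zero_target_divergence_gives_identical_pair(self):
        aln = simulate_codon_pair(CodonSimSpec(n_codons=100, target_dS=0.0, seed=1))
        assert all(a == b for a, b in aln.columns)

    def test_seed_determinism(self):
        spec = CodonSimSpec(n_codons=200, omega=0.5, target_dS=0.05, seed=9)
        a1 = simulate_codon_pair(spec)
        a2 = simulate_codon_pair(spec)
        assert a1.columns == a2.columns

    def test_realized_synonymous_divergence_near_target(self):
        aln = simulate_codon_pair(CodonSimSpec(n_codons=3000, omega=1.0, target_dS=0.08, seed=5))
        e = estimate_dnds(aln)
        assert e.dS == pytest.approx(0.08, abs=0.02)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            CodonSimSpec(n_codons=10, omega=-1.0)
        with pytest.raises(ValueError, match="n_codons"):
            CodonSimSpec(n_codons=0)
        with pytest.raises(ValueError, match="ts_tv_ratio"):
            CodonSimSpec(n_codons=10, ts_tv_ratio=0.0)


class TestPaperLikeFixture:
    def test_set_sizes(self, paper_fixture):
        assert len(paper_fixture.universe) == 19504
        sizes = {name: len(s) for name, s in paper_fixture.sets.items()}
        assert sizes["Receptors_80"] == 80
        assert sizes["allGPCR_420"] == 420
        assert sizes["allCDS_19504"] == 19504

    def test_planted_category_counts(self, paper_fixture):
        u = paper_fixture.universe.set_index("gene_id")
        rec = u[u.index.isin(paper_fixture.sets["Receptors_80"].members)]
        gpcr = u[u.index.isin(paper_fixture.sets["allGPCR_420"].members)]
        assert (u["pai"] == 6).sum() == 3203
        assert u["pai"].isin([7, 8]).sum() == 3443
        assert (rec["pai"] == 6).sum() == 37
        assert (gpcr["pai"] == 6).sum() == 152
        assert (rec["di"] <= 0.25).sum() == 45
        assert (u["di"] <= 0.25).sum() == 8719
        assert (u["di"] > 1).sum() == 1141
        assert rec["is_development"].sum() == 23
        assert ((rec["di"] <= 0.25) & rec["is_development"]).sum() == 18
        assert ((rec["di"] > 0.25) & rec["is_development"]).sum() == 5

    def test_hit_tables_recover_planted_ages(self, paper_fixture):
        fx = paper_fixture
        recovered = assign_pai_table(fx.hits, fx.species_map, fx.universe["gene_id"])
        assert (recovered.loc[fx.universe["gene_id"]].values == fx.universe["pai"].values).all()

    def test_boundary_identities_present_and_qualify(self, paper_fixture):
        """The fixture plants hits exactly at the 0.5 identity bound."""
        assert (paper_fixture.hits["identity"] == 0.5).any()

    def test_fixture_is_deterministic(self, paper_fixture):
        from phylodi.simulate import generate_paperlike_fixture

        again = generate_paperlike_fixture()
        pd.testing.assert_frame_equal(paper_fixture.universe, again.universe)
        pd.testing.assert_frame_equal(paper_fixture.hits, again.hits)
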