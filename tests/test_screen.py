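"""F-statistic pre-screening of SNPs and pairs before mapping."""

import numpy as np
import pytest

from rilmap import (
    SimulationConfig,
    TrueModel,
    build_genetic_map,
    marginal_screen,
    merge_candidates,
    pairwise_screen,
    simulate_phenotypes,
    simulate_ril_genotypes,
)
from rilmap.screen import CandidateSet

from conftest import make_geno, make_pheno


def sim_population(n_lines, n_chrom, markers, seed, spacing=10.0):
    gmap = build_genetic_map(n_chrom, markers, spacing, 1000)
    return simulate_ril_genotypes(gmap, SimulationConfig(n_lines=n_lines, seed=seed))


class TestMarginalScreen:
    def test_top_m_at_least_n_snps_keeps_all_polymorphic(self, small_ril):
        pheno = simulate_phenotypes(small_ril, TrueModel(population_mean=1.0, residual_sd=1.0), seed=1)
        cs = marginal_screen(small_ril, pheno, "trait", top_m=10_000)
        poly = (small_ril.maf() > 0).sum()
        assert len(cs.snps) == poly

    def test_monomorphic_excluded(self):
        geno = make_geno({"mono": [1.0] * 6, "poly": [1, -1, 1, -1, 1, -1]})
        pheno = make_pheno({f"L{i + 1}": float(i) for i in range(6)})
        cs = marginal_screen(geno, pheno, "trait")
        assert cs.snps == ["poly"]

    def test_constant_phenotype_warns_zero_scores(self):
        geno = make_geno({"s1": [1, -1, 1, -1]})
        pheno = make_pheno({f"L{i + 1}": 5.0 for i in range(4)})
        with pytest.warns(UserWarning, match="constant"):
            cs = marginal_screen(geno, pheno, "trait")
        assert cs.snp_scores["s1"] == 0.0

    def test_affine_invariance_of_scores(self, small_ril):
        model = TrueModel(
            population_mean=2.0, additive_effects={small_ril.snp_ids[3]: 1.5}, residual_sd=2.0
        )
        pheno = simulate_phenotypes(small_ril, model, seed=2)
        shifted = make_pheno_affine(pheno, c=-3.0, b=11.0)
        s1 = marginal_screen(small_ril, pheno, "trait").snp_scores
        s2 = marginal_screen(small_ril, shifted, "trait").snp_scores
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], rel=1e-9)

    def test_planted_qts_ranked_high(self):
        # one QTS at h2 ~ 0.3 among 2000 null SNPs, n = 138 lines:
        # the planted SNP lands in the top 10 in >= 95% of replicates
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            geno = sim_population(138, 10, 200, seed=1000 + rep, spacing=5.0)
            qts = geno.snp_ids[57]
            model = TrueModel(
                population_mean=0.0, additive_effects={qts: 2.0}, residual_sd=3.055,
                n_environments=1, n_replicates=1,
            )
            pheno = simulate_phenotypes(geno, model, seed=2000 + rep)
            cs = marginal_screen(geno, pheno, "trait", top_m=10)
            hits += qts in cs.snps
        assert hits / n_reps >= 0.95


def make_pheno_affine(pheno, c, b):
    from rilmap import PhenotypeTable

    df = pheno.data.copy()
    df["value"] = c * df["value"] + b
    return PhenotypeTable(df)


class TestPairwiseScreen:
    def test_two_snps_give_one_pair(self):
        geno = make_geno({"a": [1, -1, 1, -1, 1, 1], "b": [1, 1, -1, -1, 1, -1]})
        pheno = make_pheno({f"L{i + 1}": v for i, v in enumerate([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])})
        cs = pairwise_screen(geno, pheno, "trait", top_m=10)
        assert cs.pairs == [("a", "b")]

    def test_collinear_pair_skipped(self):
        geno = make_geno({"a": [1, -1, 1, -1], "b": [1, -1, 1, -1]})
        pheno = make_pheno({f"L{i + 1}": float(i) for i in range(4)})
        cs = pairwise_screen(geno, pheno, "trait", top_m=10)
        assert cs.pairs == [] and cs.n_skipped == 1

    def test_planted_interaction_with_no_marginals_ranked_first(self):
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            geno = sim_population(500, 5, 2, seed=300 + rep, spacing=50.0)
            qi, qj = geno.snp_ids[0], geno.snp_ids[5]
            model = TrueModel(
                population_mean=0.0, epistatic_effects={(qi, qj): 2.5}, residual_sd=3.0,
                n_environments=1, n_replicates=1,
            )
            pheno = simulate_phenotypes(geno, model, seed=400 + rep)
            cs = pairwise_screen(geno, pheno, "trait", top_m=5)
            hits += set(cs.pairs[0]) == {qi, qj}
        assert hits / n_reps >= 0.95

    def test_no_persistent_top_pair_under_additive_truth(self):
        tops = set()
        for rep in range(8):
            geno = sim_population(200, 4, 3, seed=600 + rep, spacing=40.0)
            model = TrueModel(
                population_mean=0.0,
                additive_effects={geno.snp_ids[0]: 2.0, geno.snp_ids[4]: -1.5},
                residual_sd=2.0, n_environments=1, n_replicates=1,
            )
            pheno = simulate_phenotypes(geno, model, seed=700 + rep)
            cs = pairwise_screen(geno, pheno, "trait", top_m=1)
            tops.add(tuple(sorted(cs.pairs[0])))
        assert len(tops) > 1  # no single pair dominates across seeds


class TestMerge:
    def test_identity_disjoint_and_overlap_counts(self):
        a = CandidateSet(snps=["s1", "s2", "s3"], snp_scores={"s1": 1, "s2": 2, "s3": 3})
        b = CandidateSet(snps=["s3", "s4", "s5", "s6"], snp_scores={"s3": 9, "s4": 1, "s5": 1, "s6": 1})
        assert merge_candidates([a, a]).snps == a.snps
        merged = merge_candidates([a, b])
        assert len(merged.snps) == 6  # 3 + 4 - 1 overlap
        assert merged.snp_scores["s3"] == 9  # max across sets

    def test_pair_orientation_normalised(self):
        a = CandidateSet(pairs=[("x", "y")], pair_scores={("x", "y"): 5.0})
        b = CandidateSet(pairs=[("y", "x")], pair_scores={("y", "x"): 7.0})
        merged = merge_candidates([a, b])
        assert merged.pairs == [("x", "y")] and merged.pair_scores[("x", "y")] == 7.0
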