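"""Two-step scan, permutation thresholds, stepwise selection and the
Gibbs-sampled mixed-model fit."""

import numpy as np
import pandas as pd
import pytest

from rilmap import (
    AssociationModel,
    PermutationConfig,
    PhenotypeTable,
    SelectedTerms,
    SimulationConfig,
    TrueModel,
    build_genetic_map,
    simulate_phenotypes,
    simulate_ril_genotypes,
)

from conftest import make_geno, make_pheno


def model_from(geno, values_by_line, **kw):
    return AssociationModel(geno, make_pheno(values_by_line, **kw), kw.get("trait", "trait"))


class TestAdditiveScan:
    def test_hand_computed_one_way_anova_f(self):
        # groups y(+1) = {2,3}, y(-1) = {-2,-3}: MSB = 25, MSW = 0.5, F = 50
        geno = make_geno({"s1": [1, 1, -1, -1]})
        m = model_from(geno, {"L1": 2.0, "L2": 3.0, "L3": -2.0, "L4": -3.0})
        scan = m.scan_additive()
        assert scan.f[0] == pytest.approx(50.0)

    def test_constant_phenotype_gives_zero_f(self):
        geno = make_geno({"s1": [1, 1, -1, -1], "s2": [1, -1, 1, -1]})
        m = model_from(geno, {f"L{i + 1}": 4.0 for i in range(4)})
        assert np.all(m.scan_additive().f == 0.0)

    def test_perfect_fit_reports_infinite_f(self):
        geno = make_geno({"s1": [1, 1, -1, -1]})
        m = model_from(geno, {"L1": 1.0, "L2": 1.0, "L3": -1.0, "L4": -1.0})
        assert np.isinf(m.scan_additive().f[0])

    def test_monomorphic_snp_is_nan(self):
        geno = make_geno({"mono": [1, 1, 1, 1], "s2": [1, -1, 1, -1]})
        m = model_from(geno, {"L1": 1.0, "L2": 0.0, "L3": 2.0, "L4": 1.0})
        scan = m.scan_additive()
        assert np.isnan(scan.f[0]) and np.isfinite(scan.f[1])

    def test_affine_and_sign_flip_invariance(self, small_ril):
        tm = TrueModel(population_mean=3.0, additive_effects={small_ril.snp_ids[7]: 2.0}, residual_sd=2.0)
        pheno = simulate_phenotypes(small_ril, tm, seed=5)
        m = AssociationModel(small_ril, pheno, "trait")
        f0 = m.scan_additive().f
        df = pheno.data.copy()
        df["value"] = -2.0 * df["value"] + 7.0
        f1 = AssociationModel(small_ril, PhenotypeTable(df), "trait").scan_additive().f
        np.testing.assert_allclose(f0, f1, rtol=1e-9)
        from rilmap import GenotypeMatrix

        flipped = GenotypeMatrix(small_ril.line_ids, small_ril.snps, -small_ril.calls)
        f2 = AssociationModel(flipped, pheno, "trait").scan_additive().f
        np.testing.assert_allclose(f0, f2, rtol=1e-9)


@pytest.fixture(scope="module")
def sim_model():
    gmap = build_genetic_map(3, 15, 8.0, 1000)
    geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=100, seed=8))
    pheno = simulate_phenotypes(
        geno, TrueModel(population_mean=0.0, residual_sd=2.0, env_effect_sd=0.5), seed=9
    )
    return AssociationModel(geno, pheno, "trait")


class TestPermutationThreshold:
    def test_reproducible_given_seed(self, sim_model):
        cfg = PermutationConfig(150, 0.05, seed=4)
        assert sim_model.permutation_threshold(cfg) == sim_model.permutation_threshold(cfg)

    def test_alpha_one_gives_minimum_of_max_f_sample(self, sim_model):
        cfg = PermutationConfig(120, 1.0, seed=6)
        thr = sim_model.permutation_threshold(cfg)
        # replay the identical permutation stream by hand
        rng = np.random.default_rng(6)
        state = sim_model._fast_scan_state(np.arange(len(sim_model.snp_ids)))
        maxes = [np.nanmax(sim_model._fast_scan_f(state, rng)) for _ in range(120)]
        assert thr == pytest.approx(min(maxes))

    def test_refuses_too_few_permutations(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_permutations=50)

    def test_fast_and_generic_paths_agree_on_observed_statistics(self, sim_model):
        cols = np.arange(len(sim_model.snp_ids))
        state = sim_model._fast_scan_state(cols)

        class Identity:
            def permutation(self, n):
                return np.arange(n)

        f_fast = sim_model._fast_scan_f(state, Identity())
        f_gen, _ = sim_model._scan_additive_f(cols, sim_model.line_idx)
        np.testing.assert_allclose(f_fast, f_gen, rtol=1e-9)


class TestEpistasisScan:
    def test_planted_interaction_detected_and_ranked_first(self):
        gmap = build_genetic_map(4, 2, 60.0, 1000)
        hits = 0
        for rep in range(25):
            geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=500, seed=30 + rep))
            qi, qj = geno.snp_ids[0], geno.snp_ids[4]
            tm = TrueModel(
                population_mean=0.0, epistatic_effects={(qi, qj): 2.5}, residual_sd=3.0
            )
            pheno = simulate_phenotypes(geno, tm, seed=60 + rep)
            m = AssociationModel(geno, pheno, "trait")
            scan = m.scan_epistasis()
            top = scan.units[int(np.nanargmax(scan.f))]
            hits += set(top) == {qi, qj}
        assert hits / 25 >= 0.95

    def test_pair_with_monomorphic_member_skipped(self):
        geno = make_geno({"mono": [1, 1, 1, 1, 1, 1], "a": [1, -1, 1, -1, 1, -1], "b": [1, 1, -1, -1, 1, -1]})
        m = model_from(geno, {f"L{i + 1}": float(i % 3) for i in range(6)})
        scan = m.scan_epistasis(pair_universe=[("mono", "a"), ("a", "b")])
        assert np.isnan(scan.f[0]) and scan.n_skipped >= 1


class TestStepwise:
    def test_single_significant_candidate_selected(self, small_ril):
        qts = small_ril.snp_ids[5]
        pheno = simulate_phenotypes(
            small_ril, TrueModel(population_mean=0.0, additive_effects={qts: 3.0}, residual_sd=1.0), seed=3
        )
        m = AssociationModel(small_ril, pheno, "trait")
        sel = m.stepwise_select([qts])
        assert sel.snps == [qts] and not sel.pairs

    def test_perfectly_collinear_candidates_keep_exactly_one(self):
        x = np.array([1, 1, -1, -1, 1, -1], dtype=float)
        geno = make_geno({"dup1": x, "dup2": x})
        y = {f"L{i + 1}": 2.0 * x[i] + 0.01 * i for i in range(6)}
        m = model_from(geno, y)
        sel = m.stepwise_select(["dup1", "dup2"])
        assert len(sel.snps) == 1

    def test_three_planted_qts_recovered(self):
        gmap = build_genetic_map(3, 12, 10.0, 1000)
        recovered = 0
        n_reps = 100
        for rep in range(n_reps):
            geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=138, seed=900 + rep))
            qts = [geno.snp_ids[2], geno.snp_ids[16], geno.snp_ids[29]]
            tm = TrueModel(
                population_mean=50.0,
                additive_effects=dict(zip(qts, [2.6, 3.0, 2.5])),
                residual_sd=5.5, env_effect_sd=1.0,
            )
            pheno = simulate_phenotypes(geno, tm, seed=1900 + rep)
            m = AssociationModel(geno, pheno, "trait")
            scan = m.scan_additive()
            thr = m.permutation_threshold(PermutationConfig(200, 0.05, seed=2900 + rep))
            scan.threshold = thr
            sig = scan.significant_units
            if not sig:
                continue
            sel = m.stepwise_select(sig)
            recovered += set(sel.snps) == set(qts)
        assert recovered / n_reps >= 0.80


class TestGibbsFit:
    def test_noise_free_additive_recovers_effects_exactly(self, small_ril):
        qts = {small_ril.snp_ids[2]: 2.0, small_ril.snp_ids[40]: -1.5}
        pheno = simulate_phenotypes(
            small_ril, TrueModel(population_mean=10.0, additive_effects=qts, residual_sd=0.0), seed=1
        )
        m = AssociationModel(small_ril, pheno, "trait")
        res = m.fit(SelectedTerms(snps=list(qts)), iterations=3000, seed=5)
        for s, a in qts.items():
            assert res.params[f"a:{s}"] == pytest.approx(a, abs=1e-3)
        assert res.params["mu"] == pytest.approx(10.0, abs=0.2)

    def test_fixed_seed_bit_identical(self, small_ril):
        pheno = simulate_phenotypes(
            small_ril,
            TrueModel(population_mean=1.0, additive_effects={small_ril.snp_ids[0]: 1.0}, residual_sd=1.0),
            seed=2,
        )
        m = AssociationModel(small_ril, pheno, "trait")
        sel = SelectedTerms(snps=[small_ril.snp_ids[0]])
        r1 = m.fit(sel, iterations=500, seed=9)
        r2 = m.fit(sel, iterations=500, seed=9)
        pd.testing.assert_series_equal(r1.params, r2.params)
        pd.testing.assert_series_equal(r1.bse, r2.bse)
        assert r1.varcomps == r2.varcomps

    def test_no_gxe_in_truth_gives_small_interaction_variance(self, small_ril):
        qi, qj = small_ril.snp_ids[4], small_ril.snp_ids[33]
        tm = TrueModel(
            population_mean=0.0,
            additive_effects={qi: 2.5, qj: -2.0},
            epistatic_effects={(qi, small_ril.snp_ids[40]): 1.5},
            residual_sd=3.0, env_effect_sd=1.0,
        )
        pheno = simulate_phenotypes(small_ril, tm, seed=7)
        m = AssociationModel(small_ril, pheno, "trait")
        res = m.fit(
            SelectedTerms(snps=[qi, qj], pairs=[(qi, small_ril.snp_ids[40])]),
            iterations=4000, seed=11,
        )
        assert res.varcomps["sigma2_ae"] < 0.10 * res.varcomps["sigma2_eps"]
        assert res.varcomps["sigma2_aae"] < 0.10 * res.varcomps["sigma2_eps"]


class TestHeritability:
    def test_h2_formula_wiring_and_total_sum(self, small_ril):
        qts = {small_ril.snp_ids[2]: 2.0}
        pheno = simulate_phenotypes(
            small_ril, TrueModel(population_mean=0.0, additive_effects=qts, residual_sd=3.0), seed=4
        )
        m = AssociationModel(small_ril, pheno, "trait")
        res = m.fit(SelectedTerms(snps=list(qts)), iterations=2000, seed=6)
        a = res.params[f"a:{small_ril.snp_ids[2]}"]
        var_x = np.var(m.X[:, 2], ddof=1)
        v_p = pheno.phenotypic_variance("trait")
        expected = 100.0 * a**2 * var_x / v_p
        assert res.h2.iloc[0] == pytest.approx(expected)
        assert res.total_h2 == pytest.approx(res.h2.sum())

    def test_zero_effect_zero_h2(self, small_ril):
        # a monomorphic-noise fit: effect ~ 0 implies h2 ~ 0 via the formula
        pheno = simulate_phenotypes(small_ril, TrueModel(population_mean=0.0, residual_sd=1.0), seed=8)
        m = AssociationModel(small_ril, pheno, "trait")
        res = m.fit(SelectedTerms(snps=[small_ril.snp_ids[10]]), iterations=2000, seed=10)
        assert res.h2.iloc[0] < 2.0

    def test_summary_mentions_key_quantities(self, small_ril):
        qts = small_ril.snp_ids[2]
        pheno = simulate_phenotypes(
            small_ril, TrueModel(population_mean=0.0, additive_effects={qts: 2.0}, residual_sd=1.0), seed=4
        )
        res = AssociationModel(small_ril, pheno, "trait").fit(
            SelectedTerms(snps=[qts]), iterations=1000, seed=2
        )
        text = res.summary()
        assert "total heritability" in text and qts in text
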