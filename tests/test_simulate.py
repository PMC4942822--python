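"""Single-seed-descent genotype simulation and saturated-model phenotypes."""

import numpy as np
import pytest

from rilmap import (
    SimulationConfig,
    TrueModel,
    build_genetic_map,
    simulate_phenotypes,
    simulate_ril_genotypes,
)
from rilmap.genmap import ChromosomeMap, GeneticMap, haldane_d, haldane_r
from rilmap.simulate import read_true_model, write_true_model


class TestGeneticMap:
    def test_even_spacing_and_physical_positions(self):
        gmap = build_genetic_map(1, 3, 10.0, 250_000)
        (c,) = gmap.chromosomes
        assert list(c.genetic_pos_cM) == [0.0, 10.0, 20.0]
        assert list(c.physical_pos_bp) == [1, 2_500_001, 5_000_001]

    def test_degenerate_and_counting(self):
        gmap = build_genetic_map(2, 1, 5.0, 1000)
        assert len(gmap.chromosomes) == 2
        assert all(c.genetic_pos_cM[0] == 0.0 for c in gmap)
        assert build_genetic_map(12, 100, 1.0, 300_000).n_markers == 1200

    @pytest.mark.parametrize("args", [(0, 3, 1.0, 1.0), (1, 0, 1.0, 1.0), (1, 3, -1.0, 1.0), (1, 3, 1.0, 0)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            build_genetic_map(*args)

    def test_haldane_round_trip(self):
        r = np.array([0.01, 0.1, 0.25, 0.4])
        assert np.allclose(haldane_r(haldane_d(r)), r)


class TestRilGenotypes:
    def test_fully_linked_markers_are_identical_columns(self):
        gmap = GeneticMap([ChromosomeMap("1", ["m1", "m2"], np.array([5.0, 5.0]), np.array([100, 200]))])
        geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=200, seed=3))
        np.testing.assert_array_equal(geno.calls[:, 0], geno.calls[:, 1])

    def test_unlinked_chromosomes_assort_independently(self):
        gmap = build_genetic_map(4, 1, 5.0, 1000)
        geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=5000, seed=5))
        r = np.corrcoef(geno.calls.T)
        off = r[np.triu_indices(4, 1)]
        assert np.mean(off**2) < 0.01

    def test_allele_frequency_converges_to_half(self):
        gmap = build_genetic_map(1, 10, 20.0, 1000)
        n = 20_000
        geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=n, seed=7))
        freq = (geno.calls == 1).mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 3 * np.sqrt(0.25 / n))

    def test_haldane_waddington_adjacent_r2(self):
        # genotype correlation of selfing-derived RILs: (1-2r)/(1+2r)
        r = 0.1
        gmap = GeneticMap(
            [ChromosomeMap("1", ["m1", "m2"], np.array([0.0, float(haldane_d(r))]), np.array([1, 1000]))]
        )
        geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=200_000, seed=13))
        r2 = np.corrcoef(geno.calls[:, 0], geno.calls[:, 1])[0, 1] ** 2
        expected = ((1 - 2 * r) / (1 + 2 * r)) ** 2
        assert abs(r2 - expected) < 0.01

    def test_seed_reproducibility_and_het_policy(self):
        gmap = build_genetic_map(2, 10, 5.0, 1000)
        cfg = SimulationConfig(n_lines=100, seed=42, missing_rate=0.03)
        g1 = simulate_ril_genotypes(gmap, cfg)
        g2 = simulate_ril_genotypes(gmap, cfg)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        # code-missing policy at F2 leaves many heterozygotes as missing
        cfg2 = SimulationConfig(n_lines=500, n_selfing_generations=1, seed=1, het_policy="code-missing")
        gm = simulate_ril_genotypes(gmap, cfg2)
        assert np.isnan(gm.calls).mean() > 0.2  # ~50% het at F2

    def test_errors(self):
        gmap = build_genetic_map(1, 2, 5.0, 1000)
        with pytest.raises(ValueError):
            simulate_ril_genotypes(GeneticMap([]), SimulationConfig(n_lines=10))
        with pytest.raises(ValueError):
            SimulationConfig(n_lines=1)


class TestPhenotypes:
    def test_degenerate_model_returns_mu(self, small_ril):
        model = TrueModel(population_mean=7.5, residual_sd=0.0)
        pheno = simulate_phenotypes(small_ril, model, seed=1)
        assert np.allclose(pheno.data["value"], 7.5)

    def test_noise_free_additive_is_two_valued(self, small_ril):
        qts = small_ril.snp_ids[0]
        model = TrueModel(population_mean=10.0, additive_effects={qts: 2.0}, residual_sd=0.0)
        pheno = simulate_phenotypes(small_ril, model, seed=1)
        x = dict(zip(small_ril.line_ids, small_ril.calls[:, 0]))
        for _, row in pheno.data.iterrows():
            assert row["value"] == pytest.approx(10.0 + 2.0 * x[row["line_id"]])

    def test_variance_decomposition(self):
        gmap = build_genetic_map(1, 2, 50.0, 1000)
        geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=20_000, seed=2))
        model = TrueModel(
            population_mean=0.0, additive_effects={geno.snp_ids[0]: 2.0},
            residual_sd=3.0, n_environments=1, n_replicates=1,
        )
        pheno = simulate_phenotypes(geno, model, seed=3)
        v = np.var(pheno.data["value"], ddof=1)
        var_x = np.var(geno.calls[:, 0], ddof=1)
        assert abs(v - (4 * var_x + 9)) < 0.3

    def test_environment_effect_shared_within_environment(self, small_ril):
        model = TrueModel(population_mean=0.0, env_effect_sd=5.0, residual_sd=0.0, n_replicates=1)
        pheno = simulate_phenotypes(small_ril, model, seed=4)
        per_env = pheno.data.groupby("environment")["value"].nunique()
        assert (per_env == 1).all()

    def test_epistatic_term_enters_as_product(self, small_ril):
        qi, qj = small_ril.snp_ids[0], small_ril.snp_ids[30]
        model = TrueModel(
            population_mean=0.0, epistatic_effects={(qi, qj): 1.5}, residual_sd=0.0,
            n_environments=1, n_replicates=1,
        )
        pheno = simulate_phenotypes(small_ril, model, seed=5)
        xi = small_ril.calls[:, small_ril.snp_ids.index(qi)]
        xj = small_ril.calls[:, small_ril.snp_ids.index(qj)]
        values = pheno.line_means("trait").loc[small_ril.line_ids].to_numpy()
        np.testing.assert_allclose(values, 1.5 * xi * xj)

    def test_unknown_qts_raises(self, small_ril):
        model = TrueModel(population_mean=0.0, additive_effects={"nope": 1.0})
        with pytest.raises(KeyError):
            simulate_phenotypes(small_ril, model, seed=1)

    def test_true_model_round_trip(self, tmp_path):
        model = TrueModel(
            population_mean=3.0, additive_effects={"a": 1.0},
            epistatic_effects={("a", "b"): 0.5}, residual_sd=2.0,
        )
        write_true_model(model, tmp_path / "tm.json")
        back = read_true_model(tmp_path / "tm.json")
        assert back == model
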