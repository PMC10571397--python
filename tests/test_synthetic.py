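"""Generators: genotypes, cohorts, covariances, residual families, simplex
sampler, phenotype composition and the two-factor design."""

import numpy as np
import pytest
from scipy import stats

from mantapy.synthetic import (
    GenotypeMatrix,
    SimplexGenerator,
    SimScenario,
    geodesic_shift,
    make_founders,
    make_sigma,
    relatedness,
    sim_binomial_snps,
    sim_mosaic_cohort,
    sim_phenotypes,
    sim_residuals,
    sim_simplex_phenotypes,
    sim_two_factor,
    simplex_point,
    simplex_sample,
)


class TestGenotypes:
    def test_binomial_doses_match_pmf(self, rng):
        G = sim_binomial_snps(20000, 1, 0.3, rng)
        counts = np.bincount(G.values[:, 0], minlength=3)
        expected = stats.binom.pmf([0, 1, 2], 2, 0.3) * 20000
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 2) > 1e-4

    def test_mean_dose_near_twice_maf(self, rng):
        G = sim_binomial_snps(50000, 1, 0.5, rng)
        assert abs(G.values.mean() - 1.0) < 0.02

    def test_maf_bounds_enforced(self, rng):
        with pytest.raises(ValueError, match="MAF"):
            sim_binomial_snps(10, 1, 0.7, rng)

    def test_seed_reproducibility(self):
        a = sim_binomial_snps(50, 20, 0.2, 123).values
        b = sim_binomial_snps(50, 20, 0.2, 123).values
        assert np.array_equal(a, b)


class TestMosaicCohorts:
    @pytest.fixture(scope="class")
    @staticmethod
    def founders():
        return make_founders(5, 30, 3000, fst=0.01, rng=77)

    def test_single_ancestor_copies_founder(self, founders):
        coh = sim_mosaic_cohort(founders, 10, A=1, block_size=500, rng=1)
        matches = [
            (coh.values[i] == founders.values).all(axis=1).any()
            for i in range(10)
        ]
        assert all(matches)

    def test_kinship_tail_decreases_with_ancestors(self, founders):
        q99 = []
        for A in (2, 4, 10):
            coh = sim_mosaic_cohort(founders, 100, A, block_size=300, rng=A)
            K = relatedness(coh)
            q99.append(np.quantile(K[np.triu_indices_from(K, 1)], 0.99))
        assert q99[0] > q99[1] > q99[2]

    def test_stratified_cohort_separates_in_pc_space(self, founders):
        from sklearn.metrics import silhouette_score

        from mantapy.evaluate import genotype_pcs

        coh = sim_mosaic_cohort(
            founders, 150, A=10, block_size=300, stratified=True, rng=5
        )
        pcs = genotype_pcs(coh, 4)
        assert silhouette_score(pcs, coh.pop_labels) > 0.5

    def test_too_few_founders_raises(self, founders):
        with pytest.raises(ValueError, match="founders"):
            sim_mosaic_cohort(founders, 5, A=10_000, rng=0)


class TestRelatedness:
    def test_duplicated_individual_matches_diagonal(self, rng):
        G = sim_binomial_snps(30, 2000, 0.3, rng)
        vals = np.vstack([G.values, G.values[:1]])  # row 30 duplicates row 0
        K = relatedness(GenotypeMatrix(vals, G.maf))
        assert np.isclose(K[0, 30], K[0, 0], rtol=1e-10)

    def test_independent_genotypes_near_identity(self, rng):
        G = sim_binomial_snps(50, 20000, 0.3, rng)
        K = relatedness(G)
        off = K[np.triu_indices_from(K, 1)]
        assert abs(off).max() < 0.1
        assert np.allclose(np.diag(K), 1.0, atol=0.05)

    def test_matches_pairwise_correlation_average(self, rng):
        G = sim_binomial_snps(8, 500, 0.4, rng)
        K = relatedness(G)
        vals = G.values.astype(float)
        poly = vals.std(0) > 0  # monomorphic variants carry no information
        Z = (vals[:, poly] - vals[:, poly].mean(0)) / vals[:, poly].std(0)
        assert np.allclose(K, Z @ Z.T / Z.shape[1])


class TestCovarianceAndResiduals:
    def test_equicorrelation_matrix(self):
        assert np.allclose(
            make_sigma(2, r=0.5), np.array([[1.0, 0.5], [0.5, 1.0]])
        )
        assert np.allclose(make_sigma(3, r=0.0), np.eye(3))

    def test_spaced_variances(self):
        sigma = make_sigma(3, r=0.0, variances=5.0)
        assert np.allclose(np.diag(sigma), [1.0, 3.0, 5.0])

    def test_random_sigma_positive_definite(self, rng):
        for seed in range(5):
            sigma = make_sigma(4, random=True, rng=seed)
            assert np.linalg.eigvalsh(sigma).min() > 0

    def test_mvnorm_sample_covariance(self, rng):
        E = sim_residuals("mvnorm", 40000, 2, sigma=make_sigma(2, r=0.5), rng=rng)
        assert np.allclose(np.cov(E.T), [[1, 0.5], [0.5, 1]], atol=0.05)

    def test_copula_uniform_marginals_before_scaling(self, rng):
        # reproduce the internal draw: uniform marginals pass a KS test
        Z = rng.standard_normal((2000, 3))
        U = stats.norm.cdf(Z)
        for j in range(3):
            assert stats.kstest(U[:, j], "uniform").pvalue > 1e-3
        E = sim_residuals("copula", 2000, 3, rng=rng)
        assert np.allclose(E.mean(0), 0.0, atol=1e-12)
        assert np.allclose(E.std(0, ddof=1), 1.0, rtol=1e-12)

    def test_mvt3_has_heavy_tails(self, rng):
        t = sim_residuals("mvt3", 20000, 1, rng=rng).ravel()
        g = sim_residuals("mvnorm", 20000, 1, rng=rng).ravel()
        assert stats.kurtosis(t) > stats.kurtosis(g) + 3

    def test_multinomial_rows_sum_to_trials(self, rng):
        E = sim_residuals("multinomial", 50, 4, n_trials=1000, rng=rng)
        assert (E.sum(axis=1) == 1000).all()


class TestSimplex:
    def test_center_of_simplex(self):
        assert np.allclose(simplex_point(3, 1.0), [1 / 3] * 3)

    def test_location_formula(self):
        assert np.allclose(simplex_point(3, 2.0), [0.5, 0.25, 0.25])

    def test_sample_mean_converges_to_p(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            p = r.dirichlet(np.ones(4))
            gen = SimplexGenerator(p=p, sigma_g=r.uniform(0.01, 0.2))
            Y = simplex_sample(gen, 40000, r)
            assert np.allclose(Y.mean(0), p, atol=0.01)
            assert np.allclose(Y.sum(1), 1.0)
            assert (Y >= 0).all()

    def test_zero_dispersion_collapses_to_p(self, rng):
        p = simplex_point(3, 2.0)
        Y = simplex_sample(SimplexGenerator(p=p, sigma_g=0.0), 10, rng)
        assert np.allclose(Y, p)

    def test_geodesic_shift_moves_toward_vertex_and_mirrors(self):
        p = simplex_point(3, 1.0)
        up = geodesic_shift(p, 0.2)
        down = geodesic_shift(p, -0.2)
        assert up[0] > p[0] > down[0]
        assert np.isclose(up.sum(), 1.0) and np.isclose(down.sum(), 1.0)

    def test_out_of_range_shift_raises(self):
        p = simplex_point(3, 1.1)
        with pytest.raises(ValueError, match="simplex"):
            geodesic_shift(p, -3.0)


class TestPhenotypes:
    def test_no_effects_returns_residuals_exactly(self, rng):
        scen = SimScenario(n=200, q=3, h2_v=0.0, h2_g=0.0, beta_pattern="null")
        Y, truth = sim_phenotypes(scen, rng=rng)
        assert np.array_equal(Y, truth["residual"])

    def test_realized_variance_fraction_exact(self, rng):
        scen = SimScenario(n=500, q=5, h2_v=0.005, n_traits_affected=1)
        Y, truth = sim_phenotypes(scen, rng=rng)
        assert abs(truth["h2_v_realized"] - 0.005) < 1e-10

    def test_structure_fraction_exact_and_needs_kinship(self, rng):
        scen = SimScenario(n=100, q=3, h2_v=0.005, h2_g=0.2)
        with pytest.raises(ValueError, match="relatedness"):
            sim_phenotypes(scen, rng=rng)
        K = np.eye(100)
        Y, truth = sim_phenotypes(scen, K=K, rng=rng)
        assert abs(truth["h2_g_realized"] - 0.2) < 1e-10

    def test_heteroscedasticity_scales_group_covariance(self):
        rng = np.random.default_rng(0)
        scen = SimScenario(
            n=60000, q=2, h2_v=0.0, beta_pattern="null", tau=4.0, r=0.4
        )
        x = rng.binomial(2, 0.5, 60000)
        Y, truth = sim_phenotypes(scen, x=x, rng=rng)
        E = truth["residual"]
        c0 = np.cov(E[x == 0].T)
        c2 = np.cov(E[x == 2].T)
        assert np.allclose(c2, 4.0 * c0, rtol=0.15)

    def test_correlation_only_mode_keeps_variances(self):
        rng = np.random.default_rng(1)
        scen = SimScenario(
            n=60000, q=2, h2_v=0.0, beta_pattern="null",
            tau=4.0, tau_mode="correlation_only", r=0.8,
        )
        x = rng.binomial(2, 0.5, 60000)
        Y, truth = sim_phenotypes(scen, x=x, rng=rng)
        E = truth["residual"]
        v0 = E[x == 0].var(axis=0)
        v2 = E[x == 2].var(axis=0)
        r0 = np.corrcoef(E[x == 0].T)[0, 1]
        r2 = np.corrcoef(E[x == 2].T)[0, 1]
        assert np.allclose(v0, v2, rtol=0.1)
        assert np.isclose(r2, r0 / 4.0, atol=0.03)

    def test_infeasible_variance_fractions_raise(self, rng):
        with pytest.raises(ValueError, match="h2_v"):
            sim_phenotypes(SimScenario(h2_v=0.5, h2_g=0.5), rng=rng)

    def test_beta_patterns(self):
        assert np.allclose(
            SimScenario(q=4, beta_pattern="proportions").beta(),
            [1.0, -1 / 3, -1 / 3, -1 / 3],
        )
        assert np.allclose(
            SimScenario(q=4, beta_pattern="spaced", beta_max=3.0,
                        n_traits_affected=3).beta(),
            [1.0, 2.0, 3.0, 0.0],
        )
        assert SimScenario(q=4, beta_pattern="null").beta().sum() == 0

    def test_simplex_phenotypes_shift_with_genotype(self, rng):
        x = np.repeat([0, 1, 2], 2000)
        Y = sim_simplex_phenotypes(x, q=3, delta=0.15, sigma_g=0.05, rng=rng)
        assert Y[x == 2, 0].mean() > Y[x == 1, 0].mean() > Y[x == 0, 0].mean()
        assert np.allclose(Y.sum(1), 1.0)


class TestTwoFactor:
    def test_balanced_cell_counts(self, rng):
        Y, design = sim_two_factor(300, 3, rng=rng)
        counts = design.groupby(["A", "B"]).size()
        assert (counts == 50).all()

    def test_b_shift_detected_in_group_means(self, rng):
        Y, design = sim_two_factor(600, 2, delta=1.0, rng=rng)
        b = design["B"].to_numpy()
        assert Y[b == "b1"].mean() > 0.5
        assert Y[b == "b2"].mean() < -0.5

    def test_indivisible_n_raises(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            sim_two_factor(100, 2, rng=rng)
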