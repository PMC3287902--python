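"""Noncentrality, analytical power and the Monte-Carlo comparison."""
import numpy as np
import pytest
from scipy import stats

from assocpower import (
    CovariateTable,
    TraitModel,
    adjusted_correlation,
    adjusted_covariance,
    analytical_power,
    compare_power,
    direct_effect,
    lambda_from_effects,
    model_residual_variance,
    noncentrality,
    power_analysis,
    simulate_genotypes_independent,
    simulate_traits,
    simulated_power,
)
from assocpower.data_model import DegenerateInputError
from assocpower.score_test import residualize_panel
from assocpower.score_test import _chi2_matrix


class TestAdjustedMoments:
    def test_covariance_reduces_to_sample_covariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        z = CovariateTable.empty(50)
        assert adjusted_covariance(a, b, z) == pytest.approx(
            np.cov(a, b, ddof=1)[0, 1], rel=1e-10
        )

    def test_covariance_symmetric_and_zero_variance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(size=30)
        z = CovariateTable(rng.normal(size=(30, 2)), ["u", "v"])
        assert adjusted_covariance(a, b, z) == pytest.approx(
            adjusted_covariance(b, a, z), rel=1e-12
        )
        assert adjusted_covariance(np.ones(30), np.ones(30), z) == pytest.approx(0.0, abs=1e-12)

    def test_correlation_extremes(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=40).astype(float)
        z = CovariateTable.empty(40)
        assert adjusted_correlation(x, x, z) == pytest.approx(1.0)
        assert adjusted_correlation(x, 2 - x, z) == pytest.approx(-1.0)

    def test_correlation_degenerate_raises(self):
        z = CovariateTable.empty(10)
        with pytest.raises(DegenerateInputError):
            adjusted_correlation(np.ones(10), np.arange(10.0), z)

    def test_null_correlations_mean_and_variance(self):
        """Independent common-SNP pairs: r ~ N(0, 1/N) approximately."""
        n, n_pairs = 697, 5_000
        rng = np.random.default_rng(4)
        mafs = rng.uniform(0.2, 0.5, size=2 * n_pairs)
        g = rng.binomial(2, mafs[np.newaxis, :], size=(n, 2 * n_pairs)).astype(float)
        g -= g.mean(axis=0)
        norms = np.linalg.norm(g, axis=0)
        r = (g[:, ::2] * g[:, 1::2]).sum(axis=0) / (norms[::2] * norms[1::2])
        assert abs(r.mean()) < 3 / np.sqrt(n * n_pairs)
        assert 0.8 / n < r.var() < 1.2 / n


class TestDirectEffect:
    def test_zero_beta(self, small_panel, small_covariates):
        x = small_panel.values[:, 0].astype(float)
        assert direct_effect(0.0, x, small_covariates, 1.0) == 0.0

    def test_sign_follows_beta(self, small_panel, small_covariates):
        x = small_panel.values[:, 0].astype(float)
        assert direct_effect(-0.5, x, small_covariates, 1.0) < 0
        assert direct_effect(0.5, x, small_covariates, 1.0) > 0

    def test_h_squared_is_variance_fraction(self):
        """Single causal SNP, no covariates: h^2 = beta^2 var(X) / s_yy."""
        n = 400
        g = simulate_genotypes_independent(np.array([0.5]), n, seed=5)
        z = CovariateTable.empty(n)
        model = TraitModel(snp_effects={"snp0": 1.0}, error_sd=np.sqrt(0.5))
        x = g.values[:, 0].astype(float)
        s_xx = adjusted_covariance(x, x, z)
        s_yy = model_residual_variance(model, g, z)
        assert s_yy == pytest.approx(0.5 + s_xx, rel=1e-12)
        h = direct_effect(1.0, x, z, s_yy)
        assert h**2 == pytest.approx(s_xx / (0.5 + s_xx), rel=1e-10)


class TestModelResidualVariance:
    def test_no_causal_is_noise_variance(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            error_sd=0.7,
        )
        assert model_residual_variance(
            model, small_panel, small_covariates
        ) == pytest.approx(0.49, rel=1e-12)

    def test_matches_empirical_residual_variance(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            snp_effects={"snp0": 0.6, "snp1": -0.4},
            error_sd=1.0,
        )
        implied = model_residual_variance(model, small_panel, small_covariates)
        reps = simulate_traits(small_panel, small_covariates, model, 2_000, seed=6)
        panel = residualize_panel(small_panel, small_covariates, reps, ["snp0"])
        emp = panel.s_yy
        # with divisor N-1 the noise part of s_YY carries N-p degrees of
        # freedom, so its finite-sample mean is slightly below the implied value
        n, p = small_panel.n_individuals, panel.design.shape[1]
        genetic = implied - model.error_sd**2
        expected_mean = genetic + model.error_sd**2 * (n - p) / (n - 1)
        se = emp.std() / np.sqrt(emp.size)
        assert abs(emp.mean() - expected_mean) < 3 * se
        assert implied == pytest.approx(expected_mean, rel=0.05)


class TestNoncentrality:
    def test_no_causal_gives_zero(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]), error_sd=1.0
        )
        nb = noncentrality("snp0", small_panel, small_covariates, model)
        assert nb.lam == 0.0
        assert nb.per_causal == []

    def test_ten_weak_correlations_are_hundredfold(self):
        """Ten causal SNPs at r = 0.1 with equal h: lambda = (N-1) h^2,
        100x (not 10x) the single-causal value."""
        n, h = 697, 0.15
        lam10 = lambda_from_effects(n, np.full(10, 0.1), np.full(10, h))
        lam1 = lambda_from_effects(n, [0.1], [h])
        assert lam10 / lam1 == pytest.approx(100.0, rel=1e-9)
        assert lam10 == pytest.approx((n - 1) * h**2, rel=1e-9)

    def test_breakdown_consistent_with_lambda(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            snp_effects={"snp0": 0.5, "snp4": -0.3},
            error_sd=1.0,
        )
        nb = noncentrality("snp2", small_panel, small_covariates, model)
        assert nb.cumulative == pytest.approx(
            sum(p[3] for p in nb.per_causal), rel=1e-10
        )
        assert nb.lam == pytest.approx(
            (small_panel.n_individuals - 1) * nb.cumulative**2, rel=1e-12
        )
        assert all(abs(p[1]) <= 1.0 for p in nb.per_causal)

    def test_self_test_matches_single_snp_formula(self):
        """Test SNP = the only causal SNP, no covariates: lambda = (N-1) h^2."""
        n = 300
        g = simulate_genotypes_independent(np.array([0.3]), n, seed=7)
        z = CovariateTable.empty(n)
        model = TraitModel(snp_effects={"snp0": 0.4}, error_sd=1.0)
        nb = noncentrality("snp0", g, z, model)
        x = g.values[:, 0].astype(float)
        h = direct_effect(0.4, x, z, model_residual_variance(model, g, z))
        assert nb.lam == pytest.approx((n - 1) * h**2, rel=1e-10)

    def test_trait_unit_invariance(self, small_panel, small_covariates):
        """lambda is unchanged by rescaling trait units (beta, sd -> c beta, c sd)."""
        kwargs = dict(covariate_effects=np.zeros(small_covariates.values.shape[1]))
        m1 = TraitModel(snp_effects={"snp0": 0.5, "snp1": 0.2}, error_sd=1.0, **kwargs)
        m2 = TraitModel(snp_effects={"snp0": 1.5, "snp1": 0.6}, error_sd=3.0, **kwargs)
        nb1 = noncentrality("snp3", small_panel, small_covariates, m1)
        nb2 = noncentrality("snp3", small_panel, small_covariates, m2)
        assert nb2.lam == pytest.approx(nb1.lam, rel=1e-10)

    def test_mean_statistic_is_one_plus_lambda(self, small_panel, small_covariates):
        """E[u^2/v] under the alternative matches the noncentral chi-square mean."""
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            snp_effects={"snp0": 0.35},
            error_sd=1.0,
        )
        lam = noncentrality("snp0", small_panel, small_covariates, model).lam
        reps = simulate_traits(small_panel, small_covariates, model, 2_000, seed=8)
        panel = residualize_panel(small_panel, small_covariates, reps, ["snp0"])
        chi2 = _chi2_matrix(panel.residual_genotypes, panel.residual_traits, panel.s_yy)[0]
        se = chi2.std() / np.sqrt(chi2.size)
        assert abs(chi2.mean() - (1 + lam)) < 3 * se + 0.02 * (1 + lam)


class TestAnalyticalPower:
    def test_zero_lambda_is_alpha(self):
        assert analytical_power(0.0, 0.05) == 0.05

    def test_monotone_in_lambda(self):
        lams = np.linspace(0, 40, 30)
        powers = [analytical_power(l, 0.05) for l in lams]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_against_sampling_oracle(self):
        """Noncentral chi-square tail checked by direct simulation."""
        lam, alpha, n_draws = 6.96, 0.05, 100_000
        draws = np.random.default_rng(9).noncentral_chisquare(1, lam, size=n_draws)
        crit = stats.chi2.ppf(1 - alpha, df=1)
        mc = (draws > crit).mean()
        se = np.sqrt(mc * (1 - mc) / n_draws)
        assert abs(analytical_power(lam, alpha) - mc) < 3 * se


class TestSimulatedPower:
    def test_deterministic_given_seed(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            snp_effects={"snp0": 0.5},
            error_sd=1.0,
        )
        a = simulated_power(small_panel, small_covariates, model, "snp0",
                            n_replicates=50, seed=10)
        b = simulated_power(small_panel, small_covariates, model, "snp0",
                            n_replicates=50, seed=10)
        assert a == b

    def test_converges_to_analytical(self, small_panel, small_covariates):
        model = TraitModel(
            covariate_effects=np.zeros(small_covariates.values.shape[1]),
            snp_effects={"snp0": 0.4},
            error_sd=1.0,
        )
        res = power_analysis(small_panel, small_covariates, model,
                             n_replicates=2_000, seed=11, test_snps=["snp0"])[0]
        se = np.sqrt(res.analytical_power * (1 - res.analytical_power) / 2_000)
        assert abs(res.simulated_power - res.analytical_power) < 3 * se + 0.01


class TestComparePower:
    def test_identical_vectors_are_hundred_percent(self):
        pairs = [(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)]
        pct, residuals = compare_power(pairs)
        assert pct == pytest.approx(100.0)
        assert all(r[2] == 0 for r in residuals)

    def test_noise_decreases_statistic(self):
        rng = np.random.default_rng(12)
        a = np.linspace(0.05, 0.95, 60)
        pct_small, _ = compare_power(list(zip(a, a + rng.normal(0, 0.02, 60))))
        pct_large, _ = compare_power(list(zip(a, a + rng.normal(0, 0.15, 60))))
        assert pct_large < pct_small < 100.0

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compare_power([(0.5, 0.2), (0.5, 0.6)])


class TestFindingFive:
    def test_common_snp_contributes_more_at_rare_snp(self):
        """Common/rare causal pair, equal beta: the common SNP's contribution to
        the test at the rare SNP exceeds the rare SNP's contribution to the
        test at the common SNP, because h_common > h_rare while r is shared."""
        rng = np.random.default_rng(13)
        n = 697
        common = rng.binomial(2, 0.4, size=n)
        rare = np.zeros(n, dtype=int)
        carriers = np.flatnonzero(common == 2)[:10]  # positively correlated
        rare[carriers] = 1
        from assocpower.data_model import GenotypeMatrix, SnpRecord

        g = GenotypeMatrix(
            np.column_stack([common, rare]),
            [f"i{k}" for k in range(n)],
            [SnpRecord("common", "1", 100), SnpRecord("rare", "2", 100)],
        )
        z = CovariateTable.empty(n)
        model = TraitModel(snp_effects={"common": 0.5, "rare": 0.5}, error_sd=1.0)
        at_rare = noncentrality("rare", g, z, model)
        at_common = noncentrality("common", g, z, model)
        contrib_common = dict((p[0], p) for p in at_rare.per_causal)["common"]
        contrib_rare = dict((p[0], p) for p in at_common.per_causal)["rare"]
        assert contrib_common[1] == pytest.approx(contrib_rare[1], rel=1e-10)  # r symmetric
        assert abs(contrib_common[2]) > abs(contrib_rare[2])  # h_common > h_rare
        assert contrib_common[3] > contrib_rare[3]
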