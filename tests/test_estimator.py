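import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from fertconv import (
    IdentificationError,
    InferenceError,
    cluster_vcov,
    fit_convergence,
    lsdv_oracle,
)

from conftest import make_sample, random_cluster_sample


class TestPointEstimates:
    def test_exact_linear_recovery_without_noise(self):
        # ratio = alpha + beta*base exactly -> OLS recovers beta to 1e-10
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 8, 40)
        sample = make_sample(
            [f"C{i % 10}" for i in range(40)], base, -0.02 - 0.05 * base
        )
        fit = fit_convergence(sample, fixed_effects=False)
        assert fit.beta == pytest.approx(-0.05, abs=1e-10)
        assert fit.alpha == pytest.approx(-0.02, abs=1e-10)

    def test_fe_absorbs_country_intercepts_exactly(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in range(6):
            gamma = rng.normal(0, 0.3)
            base = rng.uniform(1, 8, 4)
            for b in base:
                rows.append((f"G{g}", b, -0.02 - 0.05 * b + gamma))
        countries, base, ratio = zip(*rows)
        sample = make_sample(list(countries), list(base), list(ratio))
        fit = fit_convergence(sample, fixed_effects=True)
        assert fit.beta == pytest.approx(-0.05, abs=1e-10)

    def test_no_within_variation_is_unidentified(self):
        sample = make_sample(
            ["A", "A", "B", "B"], [4.0, 4.0, 6.0, 6.0], [-0.1, -0.2, -0.1, -0.3]
        )
        with pytest.raises(IdentificationError):
            fit_convergence(sample, fixed_effects=True)

    def test_single_cluster_raises_inference_error(self):
        sample = make_sample(["A"] * 5, [1.0, 2, 3, 4, 5], [-0.1] * 5)
        with pytest.raises(InferenceError):
            fit_convergence(sample, fixed_effects=True)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_within_matches_lsdv(self, seed):
        rng = np.random.default_rng(seed)
        sample = random_cluster_sample(rng)
        fit = fit_convergence(sample, fixed_effects=True)
        oracle = lsdv_oracle(sample)
        assert fit.beta == pytest.approx(oracle.beta, rel=1e-8)
        assert fit.se == pytest.approx(oracle.se, rel=1e-8)
        assert fit.alpha == pytest.approx(oracle.alpha, rel=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_within_matches_lsdv_with_covariates(self, seed):
        rng = np.random.default_rng(100 + seed)
        sample = random_cluster_sample(rng, n_covs=2)
        fit = fit_convergence(sample, fixed_effects=True)
        oracle = lsdv_oracle(sample)
        assert fit.beta == pytest.approx(oracle.beta, rel=1e-8)
        assert fit.se == pytest.approx(oracle.se, rel=1e-8)

    def test_one_country_slope_is_plain_ols(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 8, 6)
        ratio = -0.02 - 0.05 * base + rng.normal(0, 0.02, 6)
        sample = make_sample(["A"] * 6, base, ratio)
        oracle = lsdv_oracle(sample, compute_se=False)
        slope = np.polyfit(base, ratio, 1)[0]
        assert oracle.beta == pytest.approx(slope, rel=1e-10)

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(4)
        sample = random_cluster_sample(rng, n_clusters=6, n_per=5)
        # build a covariate orthogonal (within-demeaned) to base fertility
        data = sample.data
        demeaned = (
            data.groupby("country")["base_fertility"]
            .transform(lambda x: x - x.mean())
            .to_numpy()
        )
        z = rng.normal(size=len(data))
        z_dm = z - pd.Series(z).groupby(data["country"].values).transform("mean").values
        z_orth = z_dm - demeaned * (z_dm @ demeaned) / (demeaned @ demeaned)
        data = data.assign(z=z_orth)
        with_cov = make_sample(
            data["country"].tolist(),
            data["base_fertility"].to_numpy(),
            data["ratio"].to_numpy(),
            z=data["z"].to_numpy(),
        )
        beta_with = lsdv_oracle(with_cov).beta
        beta_without = lsdv_oracle(sample).beta
        assert beta_with == pytest.approx(beta_without, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_statsmodels_cluster_ols_agrees(self, seed):
        # external cross-check: explicit-dummy OLS with Stata-style clustered
        # covariance and t(G-1) intervals
        rng = np.random.default_rng(200 + seed)
        sample = random_cluster_sample(rng)
        y = sample.data["ratio"].to_numpy()
        X = np.column_stack(
            [
                sample.data["base_fertility"].to_numpy(),
                pd.get_dummies(sample.data["country"]).to_numpy(dtype=float),
            ]
        )
        res = sm.OLS(y, X).fit(
            cov_type="cluster",
            cov_kwds={"groups": sample.data["country"].to_numpy()},
            use_t=True,
        )
        fit = fit_convergence(sample, fixed_effects=True)
        assert fit.beta == pytest.approx(res.params[0], rel=1e-8)
        assert fit.se == pytest.approx(res.bse[0], rel=1e-8)
        ci = res.conf_int()[0]
        assert fit.ci_low == pytest.approx(ci[0], rel=1e-6)
        assert fit.ci_high == pytest.approx(ci[1], rel=1e-6)


class TestClusterVcov:
    def test_singleton_clusters_reduce_to_hc1(self):
        rng = np.random.default_rng(5)
        n = 30
        X = np.column_stack([np.ones(n), rng.uniform(1, 8, n)])
        y = X @ [0.1, -0.05] + rng.normal(0, 0.1, n)
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ coef
        v = cluster_vcov(X, resid, np.arange(n))
        res = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(v, res.cov_params(), rtol=1e-10)

    def test_duplicating_observations_rescales_se_via_cr1_only(self):
        # doubling every row leaves bread*meat*bread unchanged; only the CR1
        # small-sample factor moves, through its N-dependence
        rng = np.random.default_rng(6)
        sample = random_cluster_sample(rng, n_clusters=2, n_per=4)
        dup = make_sample(
            sample.data["country"].tolist() * 2,
            np.tile(sample.data["base_fertility"].to_numpy(), 2),
            np.tile(sample.data["ratio"].to_numpy(), 2),
        )
        f1 = fit_convergence(sample, fixed_effects=True)
        f2 = fit_convergence(dup, fixed_effects=True)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-10)
        n1, n2, G = 8, 16, 2
        k1, k2 = 1 + G, 1 + G
        expected = f1.se * np.sqrt(((n2 - 1) / (n2 - k2)) / ((n1 - 1) / (n1 - k1)))
        assert f2.se == pytest.approx(expected, rel=1e-10)

    def test_large_g_homoskedastic_approaches_classical_ols(self):
        # Monte-Carlo: with iid errors and many singleton-ish clusters the
        # clustered variance should track the classical one within a few %
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(300):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = X @ [0.0, 1.0] + rng.normal(0, 1.0, n)
            coef = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ coef
            v_cl = cluster_vcov(X, resid, np.arange(n))
            sigma2 = resid @ resid / (n - 2)
            v_ols = sigma2 * np.linalg.inv(X.T @ X)
            ratios.append(v_cl[1, 1] / v_ols[1, 1])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_fewer_than_two_clusters_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(InferenceError):
            cluster_vcov(X, np.zeros(4), np.zeros(4))


class TestInferenceContracts:
    def test_ci_uses_t_with_g_minus_1_df(self):
        rng = np.random.default_rng(8)
        sample = random_cluster_sample(rng, n_clusters=5, n_per=4)
        fit = fit_convergence(sample, fixed_effects=True)
        tcrit = stats.t.ppf(0.975, 4)
        assert fit.ci_low == pytest.approx(fit.beta - tcrit * fit.se, rel=1e-10)
        assert fit.df == 4

    def test_flag_requires_ci_excluding_zero(self):
        rng = np.random.default_rng(9)
        # strong convergence signal -> negative beta, CI below zero
        sample = random_cluster_sample(rng, n_clusters=20, n_per=5)
        fit = fit_convergence(sample, fixed_effects=True)
        assert fit.beta < 0
        assert fit.converged_flag == "convergence"
        assert fit.ci_low < fit.ci_high
        assert fit.se > 0

    def test_standardized_beta_invariant_to_affine_rescaling(self):
        from fertconv import standardize

        rng = np.random.default_rng(10)
        sample = random_cluster_sample(rng, n_clusters=8, n_per=5)
        rescaled = make_sample(
            sample.data["country"].tolist(),
            2.5 * sample.data["base_fertility"].to_numpy() + 1.0,
            0.3 * sample.data["ratio"].to_numpy(),
        )
        f1 = fit_convergence(standardize(sample), fixed_effects=True)
        f2 = fit_convergence(standardize(rescaled), fixed_effects=True)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-10)

    def test_result_serializes_to_flat_row(self):
        rng = np.random.default_rng(11)
        sample = random_cluster_sample(rng, n_clusters=4, n_per=4, n_covs=1)
        fit = fit_convergence(sample, fixed_effects=True)
        row = fit.to_row()
        assert "coef_x0" in row
        assert all(np.isscalar(v) or v is None for v in row.values())
        assert fit.to_json()
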