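import numpy as np
import pytest
from scipy import optimize, special
from scipy import stats as sps

from navscape.stats import (compare_models, design_matrix, dispersion_check,
                            fit_beta_regression, fit_hurdle_negbin,
                            simulate_beta_data, simulate_hurdle_data,
                            squeeze_proportions)


def beta_probit_negloglik(params, y, X):
    """Independent beta-regression log-likelihood (probit mean, log precision)."""
    beta, phi = params[:-1], np.exp(params[-1])
    mu = sps.norm.cdf(X @ beta)
    a, b = mu * phi, (1 - mu) * phi
    return -np.sum((a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
                   - special.betaln(a, b))


def hurdle_loglik_by_hand(y, X, gamma, beta, alpha):
    """Pointwise hurdle-NB2 log-likelihood from its published density."""
    p_pos = 1.0 / (1.0 + np.exp(-(X @ gamma)))
    mu = np.exp(X @ beta)
    theta = 1.0 / alpha
    nb_p = theta / (theta + mu)
    ll = np.where(y == 0, np.log1p(-p_pos), 0.0)
    pos = y > 0
    log_pmf = sps.nbinom.logpmf(y[pos], theta, nb_p[pos])
    log_trunc = np.log1p(-sps.nbinom.pmf(0, theta, nb_p[pos]))
    ll[pos] = np.log(p_pos[pos]) + log_pmf - log_trunc
    return float(ll.sum())


@pytest.fixture(scope="module")
def design_2x2():
    return design_matrix(np.repeat(["F", "M"], 250),
                         np.tile(np.repeat(["PBO", "E2V"], 125), 2))


class TestBetaRegression:
    def test_matches_brute_force_optimizer_on_toy_data(self):
        rng = np.random.default_rng(30)
        X = design_matrix(np.repeat(["F", "M"], 15))
        y = simulate_beta_data(X, [-0.8, 0.3], 20.0, "probit", rng)
        fit = fit_beta_regression(y, X, link="probit")
        res = optimize.minimize(
            beta_probit_negloglik, x0=np.array([0.0, 0.0, 1.0]),
            args=(y, np.asarray(X, float)), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_recovers_planted_coefficients_within_3se(self, design_2x2):
        rng = np.random.default_rng(31)
        truth = [-1.0, -0.05, 0.1, -0.08]
        y = simulate_beta_data(design_2x2, truth, 80.0, "probit", rng)
        fit = fit_beta_regression(y, design_2x2, link="probit")
        for term, b in zip(design_2x2.columns, truth):
            row = fit.coefficients.loc[term]
            assert abs(row["est"] - b) < 3 * row["se"]
        assert fit.precision > 0
        assert 50 < fit.precision < 120

    @pytest.mark.parametrize("link", ["probit", "logit", "cauchit"])
    def test_alternative_links_fit(self, link):
        rng = np.random.default_rng(32)
        X = design_matrix(np.repeat(["F", "M"], 100))
        y = simulate_beta_data(X, [-1.0, -0.2], 50.0, link, rng)
        fit = fit_beta_regression(y, X, link=link)
        assert fit.family == f"beta_{link}"
        assert np.isfinite(fit.loglik)

    def test_boundary_values_rejected_and_squeezed(self):
        X = design_matrix(["F", "F", "M", "M"])
        y = np.array([0.0, 0.5, 0.7, 1.0])
        with pytest.raises(ValueError):
            fit_beta_regression(y, X)
        ys = squeeze_proportions(y)
        assert (ys > 0).all() and (ys < 1).all()
        assert ys[1] == pytest.approx((0.5 * 3 + 0.5) / 4)

    def test_cis_contain_point_estimates(self, design_2x2):
        rng = np.random.default_rng(33)
        y = simulate_beta_data(design_2x2, [-1.0, 0.1, 0.0, 0.0], 60.0, "probit", rng)
        fit = fit_beta_regression(y, design_2x2)
        assert (fit.coefficients["ci_low"] <= fit.coefficients["est"]).all()
        assert (fit.coefficients["est"] <= fit.coefficients["ci_high"]).all()


class TestHurdleNegbin:
    def test_recovers_both_submodels_within_3se(self):
        rng = np.random.default_rng(40)
        X = design_matrix(np.repeat(["F", "M"], 200),
                          np.tile(np.repeat(["PBO", "E2V"], 100), 2))
        gamma = [0.8, 0.5, 0.0, 0.0]
        beta = [1.2, 0.3, 0.0, 0.0]
        y = simulate_hurdle_data(X, gamma, beta, theta=1.5, rng=rng)
        fit = fit_hurdle_negbin(y, X)
        for term, g in zip(X.columns, gamma):
            row = fit.submodels["zero"].loc[term]
            assert abs(row["est"] - g) < 3 * row["se"]
        for term, b in zip(X.columns, beta):
            row = fit.submodels["count"].loc[term]
            assert abs(row["est"] - b) < 3 * row["se"]

    def test_loglik_decomposition_matches_hand_coded_density(self):
        rng = np.random.default_rng(41)
        X = design_matrix(np.repeat(["F", "M"], 100))
        y = simulate_hurdle_data(X, [0.5, 0.3], [1.0, 0.2], theta=2.0, rng=rng)
        fit = fit_hurdle_negbin(y, X)
        gamma = fit.submodels["zero"]["est"].to_numpy()
        cp = fit.submodels["count"]["est"].to_numpy()
        by_hand = hurdle_loglik_by_hand(y, np.asarray(X, float),
                                        gamma, cp[:-1], cp[-1])
        assert fit.loglik == pytest.approx(by_hand, abs=1e-6)

    def test_all_positive_counts_rejected(self):
        X = design_matrix(["F"] * 10 + ["M"] * 10)
        with pytest.raises(ValueError):
            fit_hurdle_negbin(np.arange(1, 21), X)

    def test_all_zero_counts_rejected(self):
        X = design_matrix(["F"] * 10 + ["M"] * 10)
        with pytest.raises(ValueError):
            fit_hurdle_negbin(np.zeros(20, dtype=int), X)

    def test_zero_truncation_raises_the_mean(self):
        # E[Y | Y>0] = mu / (1 - P(0)) > mu
        import pandas as pd
        rng = np.random.default_rng(42)
        X = pd.DataFrame({"const": np.ones(4000)})
        y = simulate_hurdle_data(X, [10.0], [np.log(2.0)], theta=1.0, rng=rng)
        mu, theta = 2.0, 1.0
        p0 = sps.nbinom.pmf(0, theta, theta / (theta + mu))
        expected = mu / (1 - p0)
        assert expected > mu
        assert y.mean() == pytest.approx(expected, rel=0.05)


class TestDispersionCheck:
    def test_poisson_data_ratio_near_one(self):
        rng = np.random.default_rng(50)
        X = design_matrix(np.repeat(["F", "M"], 100))
        ratios = []
        for _ in range(200):
            mu = np.exp(np.asarray(X, float) @ np.array([1.0, 0.3]))
            ratios.append(dispersion_check(rng.poisson(mu), X)[0])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_negbin_data_is_overdispersed(self):
        rng = np.random.default_rng(51)
        X = design_matrix(np.repeat(["F", "M"], 200))
        y = simulate_hurdle_data(X, [10.0, 0.0], [1.5, 0.2], theta=1.0, rng=rng)
        ratio, chi2 = dispersion_check(y, X)
        assert ratio > 2.0
        assert chi2 > 0

    def test_deterministic_response_has_zero_ratio(self):
        X = design_matrix(["F"] * 10 + ["M"] * 10)
        y = np.full(20, 7.0)
        ratio, chi2 = dispersion_check(y, X)
        assert ratio == pytest.approx(0.0, abs=1e-12)


class TestCompareModels:
    def test_identical_models_give_zero_everything(self):
        rng = np.random.default_rng(60)
        X = design_matrix(np.repeat(["F", "M"], 50))
        y = simulate_beta_data(X, [-1.0, 0.2], 40.0, "probit", rng)
        fit = fit_beta_regression(y, X)
        cmp = compare_models(fit, fit)
        assert cmp.lrt_chi2 == pytest.approx(0.0)
        assert cmp.delta_aic == pytest.approx(0.0)
        assert cmp.df == 0

    def test_mismatched_nobs_rejected(self):
        rng = np.random.default_rng(61)
        X1 = design_matrix(np.repeat(["F", "M"], 30))
        X2 = design_matrix(np.repeat(["F", "M"], 40))
        f1 = fit_beta_regression(
            simulate_beta_data(X1, [-1.0, 0.0], 40.0, "probit", rng), X1)
        f2 = fit_beta_regression(
            simulate_beta_data(X2, [-1.0, 0.0], 40.0, "probit", rng), X2)
        with pytest.raises(ValueError):
            compare_models(f1, f2)

    def test_null_lrt_pvalues_uniform(self):
        # under a true null the LRT p-values should be ~Uniform(0, 1)
        rng = np.random.default_rng(62)
        X = design_matrix(np.repeat(["F", "M"], 30))
        X0 = X[["const"]]
        pvals = []
        for _ in range(400):
            y = simulate_beta_data(X, [-1.0, 0.0], 40.0, "probit", rng)
            full = fit_beta_regression(y, X)
            null = fit_beta_regression(y, X0)
            pvals.append(compare_models(full, null).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_noise_covariate_raises_aic_by_about_one(self):
        # E[ΔAIC] for one pure-noise parameter = 2 − E[χ²₁] = 1
        rng = np.random.default_rng(63)
        X = design_matrix(np.repeat(["F", "M"], 30))
        X0 = X[["const"]]
        deltas = []
        for _ in range(300):
            y = simulate_beta_data(X, [-1.0, 0.0], 40.0, "probit", rng)
            full = fit_beta_regression(y, X)
            null = fit_beta_regression(y, X0)
            deltas.append(full.aic - null.aic)
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.6)
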