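import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from greenwalk.glmm import (
    LOGISTIC_LATENT_VAR,
    FitResult,
    fit_linear_ri,
    fit_logistic_ri,
    icc,
    logistic_marginal_loglik,
    simple_slopes,
)


def _toy_logistic():
    X = np.column_stack([np.ones(6), [0.3, -1.2, 0.5, 0.9, -0.4, 1.1]])
    y = np.array([0.0, 1, 1, 0, 1, 0])
    g = np.array([0, 0, 0, 1, 1, 1], dtype=np.int64)
    return X, y, g


def _grid_loglik(beta, sigma, X, y, g):
    """Brute-force marginal log-likelihood by trapezoid integration over the
    random intercept on a fine grid — the independent quadrature oracle."""
    b = np.linspace(-10 * sigma - 5, 10 * sigma + 5, 40001)
    total = 0.0
    for j in np.unique(g):
        idx = g == j
        eta = X[idx] @ beta
        ll = (y[idx, None] * (eta[:, None] + b) - np.logaddexp(0, eta[:, None] + b)).sum(0)
        dens = np.exp(ll) * np.exp(-(b**2) / (2 * sigma**2)) / np.sqrt(2 * np.pi * sigma**2)
        total += np.log(np.trapezoid(dens, b))
    return total


@pytest.mark.parametrize("sigma", [0.3, 0.8, 1.5])
def test_adaptive_quadrature_matches_grid_integration(sigma):
    X, y, g = _toy_logistic()
    beta = np.array([0.25, -0.6])
    ll, _ = logistic_marginal_loglik(beta, np.log(sigma), X, y, g, 2, n_quad=15)
    assert ll == pytest.approx(_grid_loglik(beta, sigma, X, y, g), abs=1e-6)


def test_quadrature_order_converged_at_default():
    X, y, g = _toy_logistic()
    beta = np.array([0.1, 0.4])
    l15, _ = logistic_marginal_loglik(beta, np.log(0.7), X, y, g, 2, n_quad=15)
    l51, _ = logistic_marginal_loglik(beta, np.log(0.7), X, y, g, 2, n_quad=51)
    assert abs(l15 - l51) < 1e-6


def test_sigma_zero_reduces_to_plain_logistic():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta_true = np.array([0.2, -0.7, 0.4])
    y = (rng.random(n) < expit(X @ beta_true)).astype(float)
    g = rng.integers(0, 20, n)
    ours = fit_logistic_ri(X, y, g, sigma_fixed=0.0)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-7)
    assert np.allclose(ours.se.to_numpy(), ref.bse, atol=1e-6)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)


def test_logistic_ri_recovers_truth_and_matches_reference_fitter():
    """Moderate-size simulated mixed logistic data: our AGQ fit agrees with
    an independent implementation (statsmodels BinomialBayesMixedGLM is
    approximate, so compare against truth and the grid-evaluated likelihood
    at the optimum instead)."""
    rng = np.random.default_rng(6)
    n, J = 4000, 80
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta_true = np.array([0.3, 0.5, -0.4])
    sigma_true = 0.7
    g = rng.integers(0, J, n)
    b = rng.normal(0, sigma_true, J)
    y = (rng.random(n) < expit(X @ beta_true + b[g])).astype(float)
    fit = fit_logistic_ri(X, y, g)
    assert fit.converged
    assert np.all(np.abs(fit.params.to_numpy() - beta_true) < 4 * fit.se.to_numpy() + 0.05)
    assert abs(fit.sigma_u - sigma_true) < 0.2
    # the optimum must not be improved by nudging any coordinate
    theta = np.append(fit.params.to_numpy(), np.log(fit.sigma_u))
    ll_opt, _ = logistic_marginal_loglik(theta[:-1], theta[-1], X, y, g.astype(np.int64), J)
    for i in range(len(theta)):
        for d in (-0.02, 0.02):
            t = theta.copy()
            t[i] += d
            ll_perturbed, _ = logistic_marginal_loglik(t[:-1], t[-1], X, y, g.astype(np.int64), J)
            assert ll_perturbed <= ll_opt + 1e-6


def _dense_linear_loglik(params, X, y, g, J):
    """Direct multivariate-normal log-likelihood with per-group dense
    covariance matrices — the independent linear-model oracle."""
    beta = params[:-2]
    sb, se = np.exp(params[-2]), np.exp(params[-1])
    total = 0.0
    r = y - X @ beta
    for j in range(J):
        idx = np.flatnonzero(g == j)
        V = sb**2 * np.ones((len(idx), len(idx))) + se**2 * np.eye(len(idx))
        sign, logdet = np.linalg.slogdet(V)
        rj = r[idx]
        total += -0.5 * (len(idx) * np.log(2 * np.pi) + logdet + rj @ np.linalg.solve(V, rj))
    return total


def test_linear_ri_matches_dense_ml_oracle():
    rng = np.random.default_rng(7)
    n, J = 300, 15
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    g = rng.integers(0, J, n)
    y = X @ [1.0, 0.5, -0.3] + rng.normal(0, 0.6, J)[g] + rng.normal(0, 0.9, n)
    fit = fit_linear_ri(X, y, g)
    params = np.concatenate(
        [fit.params.to_numpy(), [np.log(fit.sigma_b), np.log(fit.sigma_e)]]
    )
    ll_dense = _dense_linear_loglik(params, X, y, g, J)
    assert fit.loglik == pytest.approx(ll_dense, abs=1e-8)
    # and it is the maximizer of the dense likelihood too
    from scipy.optimize import minimize

    res = minimize(lambda p: -_dense_linear_loglik(p, X, y, g, J), params, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    assert -res.fun <= fit.loglik + 1e-6
    assert np.allclose(res.x[:3], fit.params.to_numpy(), atol=1e-4)


def test_linear_ri_matches_statsmodels_mixedlm():
    smm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
    rng = np.random.default_rng(8)
    n, J = 1200, 40
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    g = rng.integers(0, J, n)
    y = X @ [0.2, 0.4, -0.5] + rng.normal(0, 0.5, J)[g] + rng.normal(0, 1.0, n)
    ours = fit_linear_ri(X, y, g)
    ref = smm.MixedLM(y, X, groups=g).fit(reml=False)
    assert np.allclose(ours.params.to_numpy(), ref.fe_params, atol=1e-5)
    assert ours.sigma_e**2 == pytest.approx(ref.scale, rel=1e-3)
    assert ours.sigma_b**2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-2, abs=1e-4)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)


def test_sigma_b_zero_reduces_to_ols():
    rng = np.random.default_rng(9)
    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ [1.0, -0.2, 0.7] + rng.normal(0, 1.0, n)
    g = rng.integers(0, 25, n)  # grouping unrelated to y
    fit = fit_linear_ri(X, y, g, sigma_b_fixed=0.0)
    ols = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.sigma_b == 0.0
    assert np.allclose(fit.params.to_numpy(), ols, atol=1e-10)
    # ML residual variance (divisor n) and the exact OLS log-likelihood
    resid = y - X @ ols
    sig2 = resid @ resid / n
    ll = -0.5 * n * (np.log(2 * np.pi * sig2) + 1)
    assert fit.loglik == pytest.approx(ll, abs=1e-8)
    # unconstrained fit on unrelated grouping stays near OLS too
    free = fit_linear_ri(X, y, g)
    assert np.allclose(free.params.to_numpy(), ols, atol=2e-2)


def test_balanced_design_closed_form_anova_components():
    """Equal group sizes admit closed-form ML variance components from the
    one-way ANOVA sums of squares; the profiled fit must reproduce them."""
    rng = np.random.default_rng(10)
    J, m = 30, 12
    n = J * m
    g = np.repeat(np.arange(J), m)
    y = rng.normal(0, 0.8, J)[g] + rng.normal(0, 1.1, n)
    X = np.ones((n, 1))
    fit = fit_linear_ri(X, y, g)
    ybar_j = np.array([y[g == j].mean() for j in range(J)])
    ybar = y.mean()
    ssw = float(((y - ybar_j[g]) ** 2).sum())
    ssb = float(m * ((ybar_j - ybar) ** 2).sum())
    sigma_e2 = ssw / (n - J)
    sigma_b2 = max(0.0, (ssb / J) / m - sigma_e2 / m)  # ML, balanced case
    assert fit.params.iloc[0] == pytest.approx(ybar, abs=1e-8)
    assert fit.sigma_e**2 == pytest.approx(sigma_e2, rel=1e-6)
    assert fit.sigma_b**2 == pytest.approx(sigma_b2, rel=1e-5)


def test_aic_bic_identities():
    rng = np.random.default_rng(11)
    n, J = 600, 20
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    g = rng.integers(0, J, n)
    y_bin = (rng.random(n) < expit(0.3 * X[:, 1] + rng.normal(0, 0.5, J)[g])).astype(float)
    fit = fit_logistic_ri(X, y_bin, g)
    p = fit.n_params
    assert fit.aic == pytest.approx(2 * p - 2 * fit.loglik)
    assert fit.bic == pytest.approx(p * np.log(n) - 2 * fit.loglik)


def _mk_fit(family, **kw):
    base = dict(
        family=family,
        params=pd.Series({"x": 0.0}),
        se=pd.Series({"x": 1.0}),
        cov=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
        loglik=0.0,
        n_params=1,
        n_obs=10,
        n_groups=2,
        converged=True,
    )
    base.update(kw)
    return FitResult(**base)


def test_icc_algebra():
    assert icc(_mk_fit("gaussian", sigma_b=1.3, sigma_e=1.3)) == pytest.approx(0.5)
    assert icc(_mk_fit("binomial-logit", sigma_u=0.0)) == 0.0
    assert icc(
        _mk_fit("binomial-logit", sigma_u=float(np.sqrt(LOGISTIC_LATENT_VAR)))
    ) == pytest.approx(0.5)


def test_fitted_icc_increases_with_generating_sigma():
    rng = np.random.default_rng(12)
    n, J = 4000, 80
    g = rng.integers(0, J, n)
    X = np.ones((n, 1))
    iccs = []
    for sigma in (0.3, 0.7, 1.3):
        vals = []
        for rep in range(3):
            b = rng.normal(0, sigma, J)
            y = (rng.random(n) < expit(b[g])).astype(float)
            vals.append(fit_logistic_ri(X, y, g).icc)
        iccs.append(np.mean(vals))
    assert iccs[0] < iccs[1] < iccs[2]


def test_simple_slopes_zero_interaction_equals_main():
    cov = pd.DataFrame(np.eye(2) * 0.01, index=["gvi", "gvi_x_gender"], columns=["gvi", "gvi_x_gender"])
    fit = _mk_fit(
        "binomial-logit",
        params=pd.Series({"gvi": 0.2, "gvi_x_gender": 0.0}),
        se=pd.Series({"gvi": 0.1, "gvi_x_gender": 0.1}),
        cov=cov,
        sigma_u=0.5,
    )
    tab = simple_slopes(fit, "gvi", "gvi_x_gender")
    assert tab.loc["female", "OR"] == pytest.approx(np.exp(0.2))
    assert tab.loc["male", "OR"] == pytest.approx(np.exp(0.2))


def test_simple_slopes_error_when_term_missing():
    fit = _mk_fit("binomial-logit", sigma_u=0.1)
    with pytest.raises(ValueError):
        simple_slopes(fit, "x", "not_there")


def test_simple_slope_se_matches_reparameterized_refit():
    """Delta-method SE of the female slope equals the direct SE from the
    equivalent model parameterized with per-gender slope columns."""
    rng = np.random.default_rng(13)
    n, J = 3000, 50
    female = (rng.random(n) < 0.5).astype(float)
    zg = rng.normal(size=n)
    g = rng.integers(0, J, n)
    eta = 0.1 + 0.25 * zg + 0.4 * female + 0.12 * zg * (female - 0.5) + rng.normal(0, 0.5, J)[g]
    y = (rng.random(n) < expit(eta)).astype(float)

    X_int = pd.DataFrame(
        {"intercept": 1.0, "gvi": zg, "female": female, "gvi_x_gender": zg * (female - 0.5)}
    )
    fit_int = fit_logistic_ri(X_int, y, g)
    tab = simple_slopes(fit_int, "gvi", "gvi_x_gender")

    X_strat = pd.DataFrame(
        {"intercept": 1.0, "gvi_male": zg * (1 - female), "gvi_female": zg * female, "female": female}
    )
    fit_strat = fit_logistic_ri(X_strat, y, g)
    assert np.log(tab.loc["female", "OR"]) == pytest.approx(
        fit_strat.params["gvi_female"], abs=2e-4
    )
    se_delta = (np.log(tab.loc["female", "ci_high"]) - np.log(tab.loc["female", "OR"])) / 1.959963984540054
    assert se_delta == pytest.approx(fit_strat.se["gvi_female"], rel=5e-3)


def test_input_validation():
    X = np.ones((10, 1))
    with pytest.raises(ValueError):
        fit_logistic_ri(X, np.arange(10), np.zeros(10))  # non-binary y
    with pytest.raises(ValueError):
        fit_logistic_ri(X, np.full(10, np.nan), np.zeros(10))
    with pytest.raises(ValueError):
        fit_linear_ri(X, np.zeros(10), np.arange(10))  # singleton groups
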