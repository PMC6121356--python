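"""Random-intercept multilevel models, fitted from scratch.

Two families:

* binomial-logit with a Gaussian random intercept per group, fitted by
  maximizing the marginal likelihood with adaptive (mode-centered,
  curvature-scaled) Gauss-Hermite quadrature;
* gaussian with a random intercept, fitted by profiled maximum likelihood
  (closed-form GLS for the fixed effects given the variance ratio, 1-D
  optimization of the ratio); REML available by flag.

Gradients of the logistic marginal log-likelihood are computed analytically
through the Fisher identity (posterior expectations at the quadrature nodes),
which keeps n ~ 25,000 x 200-group fits at interactive speed.  Standard
errors come from the observed information (numerically differentiated
analytic gradient); confidence intervals and p-values are Wald.  The
intraclass correlation uses the variance ratio for the gaussian family and
the latent-threshold convention (residual variance pi^2/3) for the logistic.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

__all__ = [
    "FitResult",
    "fit_logistic_ri",
    "fit_linear_ri",
    "icc",
    "simple_slopes",
    "logistic_marginal_loglik",
]

LOGISTIC_LATENT_VAR = np.pi**2 / 3.0


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and inference for one random-intercept fit."""

    family: str  # "binomial-logit" | "gaussian"
    params: pd.Series  # fixed effects
    se: pd.Series
    cov: pd.DataFrame  # covariance of fixed effects (+ log sigma_u for logit)
    loglik: float
    n_params: int  # fixed effects + variance components
    n_obs: int
    n_groups: int
    converged: bool
    sigma_u: float | None = None  # logistic random-intercept SD (latent scale)
    sigma_b: float | None = None  # gaussian between-group SD
    sigma_e: float | None = None  # gaussian residual SD
    message: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2 * self.loglik

    @property
    def icc(self) -> float:
        return icc(self)

    def z_values(self) -> pd.Series:
        return self.params / self.se

    def p_values(self) -> pd.Series:
        return pd.Series(
            2 * norm.sf(np.abs(self.z_values())), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.se, "high": self.params + z * self.se}
        )

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Exponentiated coefficients with Wald CIs (logistic reporting)."""
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
                "p": self.p_values(),
            }
        )

    def beta_table(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "beta": self.params,
                "ci_low": ci["low"],
                "ci_high": ci["high"],
                "p": self.p_values(),
            }
        )

    def summary(self) -> str:
        tab = self.or_table() if self.family == "binomial-logit" else self.beta_table()
        lines = [
            f"Random-intercept {self.family} model"
            f"  (n_obs={self.n_obs}, n_groups={self.n_groups})",
            tab.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.family == "binomial-logit":
            lines.append(f"sigma_u = {self.sigma_u:.4f}   ICC = {self.icc:.4f}")
        else:
            lines.append(
                f"sigma_b = {self.sigma_b:.4f}  sigma_e = {self.sigma_e:.4f}"
                f"   ICC = {self.icc:.4f}"
            )
        lines.append(
            f"logLik = {self.loglik:.2f}  AIC = {self.aic:.1f}  BIC = {self.bic:.1f}"
        )
        return "\n".join(lines)


def icc(fit: FitResult) -> float:
    """Intraclass correlation of a fitted model.

    Gaussian: sigma_b^2 / (sigma_b^2 + sigma_e^2).  Binomial-logit:
    sigma_u^2 / (sigma_u^2 + pi^2/3), the latent-threshold convention.
    """
    if fit.family == "gaussian":
        vb, ve = fit.sigma_b**2, fit.sigma_e**2
        return float(vb / (vb + ve)) if (vb + ve) > 0 else 0.0
    vu = fit.sigma_u**2
    return float(vu / (vu + LOGISTIC_LATENT_VAR))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(np.int64), len(uniques)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + e^eta), stable
    return y * eta - np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# logistic random intercept via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


def _group_modes(
    eta: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    J: int,
    sigma2: float,
    b0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton mode and curvature of the per-group conditional posterior.

    Maximizes h_j(b) = sum_i log Bernoulli(y_ij | eta_ij + b) - b^2/(2 sigma^2)
    for all groups simultaneously.  Returns (mode, -h'' at mode).
    """
    b = b0.copy()
    for _ in range(max_iter):
        mu = special.expit(eta + b[g])
        grad = np.bincount(g, weights=y - mu, minlength=J) - b / sigma2
        w = np.bincount(g, weights=mu * (1 - mu), minlength=J) + 1.0 / sigma2
        step = grad / w
        # dampen huge steps (separated groups)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    mu = special.expit(eta + b[g])
    curv = np.bincount(g, weights=mu * (1 - mu), minlength=J) + 1.0 / sigma2
    return b, curv


def logistic_marginal_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    J: int,
    n_quad: int = 15,
    b0: np.ndarray | None = None,
    want_grad: bool = False,
):
    """Adaptive-GHQ marginal log-likelihood (and analytic gradient).

    The gradient uses the Fisher identity: d/dtheta log L_j equals the
    posterior expectation of the complete-data score, evaluated with the same
    quadrature nodes reweighted to posterior weights — exact up to quadrature
    error regardless of how the nodes were centered.
    """
    sigma = float(np.exp(log_sigma))
    sigma2 = sigma**2
    eta = X @ beta
    if b0 is None:
        b0 = np.zeros(J)
    b_hat, curv = _group_modes(eta, y, g, J, sigma2, b0)
    tau = 1.0 / np.sqrt(curv)  # Laplace scale per group

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    # probabilists' nodes: integral f(b) db ~ sum_k w_k e^{z_k^2/2} f(bhat + tau z_k) * tau
    log_wk = np.log(weights) + 0.5 * nodes**2

    n = len(y)
    l_nodes = np.empty((J, n_quad))
    for k in range(n_quad):
        b_k = b_hat + tau * nodes[k]
        ll_i = _bernoulli_loglik(eta + b_k[g], y)
        prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * b_k**2 / sigma2
        l_nodes[:, k] = (
            np.bincount(g, weights=ll_i, minlength=J) + prior + log_wk[k] + np.log(tau)
        )
    m = l_nodes.max(axis=1)
    lse = m + np.log(np.exp(l_nodes - m[:, None]).sum(axis=1))
    ll = float(lse.sum())
    if not want_grad:
        return ll, b_hat

    post = np.exp(l_nodes - lse[:, None])  # (J, K) posterior node weights
    resid_bar = np.zeros(n)
    grad_ls = 0.0
    for k in range(n_quad):
        b_k = b_hat + tau * nodes[k]
        mu_k = special.expit(eta + b_k[g])
        resid_bar += post[g, k] * (y - mu_k)
        grad_ls += float(post[:, k] @ (b_k**2 / sigma2 - 1.0))
    grad_beta = X.T @ resid_bar
    grad = np.append(grad_beta, grad_ls)
    return ll, b_hat, grad


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Plain logistic regression by iteratively reweighted least squares
    (starting values for the mixed fit)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def fit_logistic_ri(
    X,
    y,
    groups,
    n_quad: int = 15,
    gtol: float = 1e-6,
    max_restarts: int = 3,
    sigma_fixed: float | None = None,
) -> FitResult:
    """Random-intercept logistic regression via adaptive Gauss-Hermite
    quadrature.

    ``X`` should include an intercept column.  ``sigma_fixed`` pins the
    random-intercept SD (0 reduces the model to plain logistic regression).
    """
    Xa, names = _as_design(X)
    ya = np.asarray(y, dtype=float)
    if not np.isin(ya, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values in design or outcome")
    g, J = _group_codes(groups)
    if J < 2 and sigma_fixed is None:
        raise ValueError("grouping factor needs >= 2 levels")
    p = Xa.shape[1]
    n = len(ya)

    if sigma_fixed is not None and sigma_fixed <= 0:
        # exact reduction: plain logistic regression
        beta = _irls_logistic(Xa, ya)
        eta = Xa @ beta
        mu = special.expit(eta)
        ll = float(_bernoulli_loglik(eta, ya).sum())
        W = mu * (1 - mu)
        info = Xa.T @ (Xa * W[:, None])
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        return FitResult(
            family="binomial-logit",
            params=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            loglik=ll,
            n_params=p,
            n_obs=n,
            n_groups=J,
            converged=True,
            sigma_u=0.0,
        )

    b_cache = {"b": np.zeros(J)}

    fix_sigma = sigma_fixed is not None

    def negloglik_grad(theta):
        beta = theta[:p]
        ls = np.log(sigma_fixed) if fix_sigma else theta[p]
        ll, b_hat, grad = logistic_marginal_loglik(
            beta, ls, Xa, ya, g, J, n_quad, b0=b_cache["b"], want_grad=True
        )
        b_cache["b"] = b_hat
        if fix_sigma:
            return -ll, -grad[:p]
        return -ll, -grad

    beta0 = _irls_logistic(Xa, ya)
    x0 = beta0 if fix_sigma else np.append(beta0, np.log(0.5))

    rng = np.random.default_rng(0)
    res = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.1, size=len(x0))
        res = optimize.minimize(
            negloglik_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-12, "maxiter": 500},
        )
        if res.success:
            break

    theta = res.x
    beta = theta[:p]
    log_sigma = np.log(sigma_fixed) if fix_sigma else theta[p]
    sigma_u = float(np.exp(log_sigma))
    ll = -float(res.fun)

    # observed information: central differences of the analytic gradient
    dim = len(theta)

    def grad_only(t):
        return negloglik_grad(t)[1]

    H = np.empty((dim, dim))
    h = 1e-5 * (1.0 + np.abs(theta))
    for i in range(dim):
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        H[:, i] = (grad_only(tp) - grad_only(tm)) / (2 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    idx_names = names + ([] if fix_sigma else ["log_sigma_u"])
    se_full = np.sqrt(np.clip(np.diag(cov_full), 0, None))

    return FitResult(
        family="binomial-logit",
        params=pd.Series(beta, index=names),
        se=pd.Series(se_full[:p], index=names),
        cov=pd.DataFrame(cov_full, index=idx_names, columns=idx_names),
        loglik=ll,
        n_params=p + (0 if fix_sigma else 1),
        n_obs=n,
        n_groups=J,
        converged=bool(res.success),
        sigma_u=sigma_u,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# gaussian random intercept by profiled ML / REML
# ---------------------------------------------------------------------------


def _linear_profile(loglam: float, Xa, ya, g, J, counts, reml: bool):
    """Profiled quantities at variance ratio lambda = sigma_b^2/sigma_e^2."""
    lam = np.exp(loglam)
    n, p = Xa.shape
    c = lam / (1.0 + lam * counts)  # (J,)
    Sx = np.zeros((J, p))
    np.add.at(Sx, g, Xa)
    Sy = np.bincount(g, weights=ya, minlength=J)
    A = Xa.T @ Xa - Sx.T @ (Sx * c[:, None])
    bvec = Xa.T @ ya - Sx.T @ (c * Sy)
    beta = np.linalg.solve(A, bvec)
    r = ya - Xa @ beta
    Sr = np.bincount(g, weights=r, minlength=J)
    quad = float(r @ r - (c * Sr) @ Sr)
    logdet_v = float(np.log1p(lam * counts).sum())  # log|V|/sigma_e^2 part
    if reml:
        sig2 = quad / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sig2)
            + logdet_v
            + (n - p)
            + logdet_a
            - p * np.log(sig2)
        )
    else:
        sig2 = quad / n
        ll = -0.5 * (n * np.log(2 * np.pi * sig2) + logdet_v + n)
    return ll, beta, sig2, A


def fit_linear_ri(
    X, y, groups, reml: bool = False, sigma_b_fixed: float | None = None
) -> FitResult:
    """Random-intercept linear regression by profiled maximum likelihood.

    Given the variance ratio lambda = sigma_b^2/sigma_e^2, the GLS fixed
    effects and the residual variance have closed forms; lambda itself is
    optimized on the log scale in one dimension.  ``reml=True`` switches the
    criterion to restricted ML (AIC/BIC are reported for the chosen
    criterion's likelihood).  ``sigma_b_fixed=0`` constrains the model to
    ordinary (independent-errors) regression.
    """
    Xa, names = _as_design(X)
    ya = np.asarray(y, dtype=float)
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values in design or outcome")
    g, J = _group_codes(groups)
    if J < 2:
        raise ValueError("grouping factor needs >= 2 levels")
    counts = np.bincount(g, minlength=J).astype(float)
    n, p = Xa.shape
    if sigma_b_fixed is None and np.all(counts <= 1):
        raise ValueError(
            "every group has a single observation; sigma_b is not identified"
        )

    def neg(loglam):
        return -_linear_profile(loglam, Xa, ya, g, J, counts, reml)[0]

    if sigma_b_fixed is not None:
        if sigma_b_fixed != 0:
            raise NotImplementedError("only sigma_b_fixed=0 is supported")
        loglam = -np.inf
    else:
        res = optimize.minimize_scalar(
            neg, bounds=(-14.0, 10.0), method="bounded", options={"xatol": 1e-10}
        )
        # compare against the boundary lambda -> 0 (plain OLS)
        ll_bnd = -neg(-30.0)
        loglam = -30.0 if ll_bnd > -res.fun + 1e-10 else float(res.x)
    ll, beta, sig2, A = _linear_profile(loglam, Xa, ya, g, J, counts, reml)
    lam = np.exp(loglam)
    sigma_e = float(np.sqrt(sig2))
    sigma_b = float(np.sqrt(lam * sig2))
    cov = sig2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        family="gaussian",
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(ll),
        n_params=p + (1 if sigma_b_fixed == 0 else 2),
        n_obs=n,
        n_groups=J,
        converged=True,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
    )


# ---------------------------------------------------------------------------
# post-hoc simple slopes
# ---------------------------------------------------------------------------


def simple_slopes(
    fit: FitResult,
    main: str,
    interaction: str,
    coding: dict[str, float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Stratum-specific slopes from a model with a moderator interaction.

    For each stratum with coding weight c, the slope is beta_main +
    c * beta_interaction; its SE follows from the coefficient covariance by
    the delta method (linear combination, so exact).  Logistic fits are
    reported on the odds-ratio scale.  Default coding is effect coding
    {-1/2, +1/2} for a binary moderator.
    """
    if interaction not in fit.params.index:
        raise ValueError(f"interaction term {interaction!r} not in model")
    if main not in fit.params.index:
        raise ValueError(f"main term {main!r} not in model")
    coding = coding or {"male": -0.5, "female": 0.5}
    z = norm.ppf(0.5 + level / 2)
    v = fit.cov
    rows = {}
    for stratum, c in coding.items():
        slope = fit.params[main] + c * fit.params[interaction]
        var = (
            v.loc[main, main]
            + c**2 * v.loc[interaction, interaction]
            + 2 * c * v.loc[main, interaction]
        )
        se = float(np.sqrt(var))
        pz = 2 * norm.sf(abs(slope / se))
        if fit.family == "binomial-logit":
            rows[stratum] = {
                "OR": float(np.exp(slope)),
                "ci_low": float(np.exp(slope - z * se)),
                "ci_high": float(np.exp(slope + z * se)),
                "p": float(pz),
            }
        else:
            rows[stratum] = {
                "beta": float(slope),
                "ci_low": float(slope - z * se),
                "ci_high": float(slope + z * se),
                "p": float(pz),
            }
    return pd.DataFrame(rows).T
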