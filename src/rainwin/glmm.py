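"""Negative-binomial random-intercept GLMM engine.

Fits models of the form

    y_i ~ NB(mu_i, theta),   log mu_i = x_i' beta + b_{g(i)},
    b_g ~ Normal(0, sigma^2)

by maximizing the marginal likelihood, with the one-dimensional
random-effect integral evaluated per group by adaptive Gauss-Hermite
quadrature centred at the conditional mode (one node = the Laplace
approximation, the default). The NB family uses the mean-dispersion
parameterization Var(y) = mu + mu^2/theta with a log link.

Wald inference for the fixed effects comes from the inverse observed
information of beta at the optimum; theta and sigma are profiled on the
log scale. A deviance-based fixed-effects R^2 (with Ezekiel small-sample
adjustment) compares a fitted model against its intercept-only null,
evaluating both deviances at population-level means (random effect at
zero) with the full model's theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_LOG_SIGMA_ZERO = -8.0  # below this, sigma is treated as exactly 0
_LOG_THETA_MAX = 11.0  # above this, the fit is flagged as the Poisson limit


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Negative-binomial deviance 2*(ll_saturated - ll(mu))."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(term1 - term2))


def _group_modes(eta0, y, gidx, n_groups, theta, sig2, b0=None):
    """Newton iteration for the per-group conditional modes of b.

    The conditional log-density is strictly concave in b, so undamped
    Newton with a step clip converges quickly from any start.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    h = None
    for _ in range(60):
        eta = np.clip(eta0 + b[gidx], -30.0, 30.0)
        mu = np.exp(eta)
        r = (y + theta) * mu / (mu + theta)
        g1 = np.bincount(gidx, weights=y - r, minlength=n_groups) - b / sig2
        h = np.bincount(gidx, weights=r * theta / (mu + theta), minlength=n_groups) + 1.0 / sig2
        step = np.clip(g1 / h, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(g1)) < 1e-9:
            break
    eta = np.clip(eta0 + b[gidx], -30.0, 30.0)
    mu = np.exp(eta)
    r = (y + theta) * mu / (mu + theta)
    h = np.bincount(gidx, weights=r * theta / (mu + theta), minlength=n_groups) + 1.0 / sig2
    return b, h


def marginal_loglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    n_quad: int = 1,
    mode_cache: dict | None = None,
) -> float:
    """Marginal log-likelihood at ``params = (beta, log theta, log sigma)``.

    With sigma at (numerical) zero this reduces exactly to the
    independent NB log-likelihood. ``mode_cache`` (a dict with key
    ``"b"``) warm-starts the inner Newton iteration across calls.
    """
    p = X.shape[1]
    beta = params[:p]
    theta = float(np.exp(params[p]))
    log_sigma = float(params[p + 1])
    eta0 = X @ beta
    if log_sigma <= _LOG_SIGMA_ZERO:
        mu = np.exp(np.clip(eta0, -30.0, 30.0))
        return float(np.sum(_nb_logpmf(y, mu, theta)))
    sigma = np.exp(log_sigma)
    sig2 = sigma * sigma
    b0 = mode_cache.get("b") if mode_cache is not None else None
    b, h = _group_modes(eta0, y, gidx, n_groups, theta, sig2, b0=b0)
    if mode_cache is not None:
        mode_cache["b"] = b
    if n_quad <= 1:
        mu = np.exp(np.clip(eta0 + b[gidx], -30.0, 30.0))
        ll_data = np.bincount(gidx, weights=_nb_logpmf(y, mu, theta), minlength=n_groups)
        ll = ll_data - b * b / (2.0 * sig2) - np.log(sigma) - 0.5 * np.log(h)
        return float(ll.sum())
    # adaptive Gauss-Hermite centred at the mode, scaled by the curvature
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    s = 1.0 / np.sqrt(h)  # (n_groups,)
    bmat = b[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]
    log_int = np.empty((n_groups, n_quad))
    for j in range(n_quad):
        mu = np.exp(np.clip(eta0 + bmat[gidx, j], -30.0, 30.0))
        ll_data = np.bincount(gidx, weights=_nb_logpmf(y, mu, theta), minlength=n_groups)
        log_prior = -0.5 * bmat[:, j] ** 2 / sig2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        log_int[:, j] = np.log(w[j]) + z[j] ** 2 + ll_data + log_prior
    ll = special.logsumexp(log_int, axis=1) + 0.5 * np.log(2.0) + np.log(s)
    return float(ll.sum())


@dataclass
class ModelSpec:
    """Specification of one NB mixed model.

    ``year`` controls how the year column enters the fixed effects:
    ``"numeric"`` (centered linear term, the default — a 6-level factor
    would alias any covariate taking one value per year, such as seasonal
    rainfall), ``"factor"`` (treatment-coded dummies) or ``None``.
    """

    response: str
    covariates: list = field(default_factory=list)
    group: str = "plot"
    year: str | None = "numeric"
    n_quad: int = 1


@dataclass
class GLMMFit:
    """Result of one NB random-intercept GLMM fit."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    theta: float
    sigma_plot: float
    loglik: float
    deviance: float
    n_obs: int
    n_groups: int
    converged: bool
    grad_norm: float
    poisson_limit: bool
    y: np.ndarray
    X: np.ndarray
    mu_pop: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, [np.log(self.theta)], [np.log(max(self.sigma_plot, 1e-8))]])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": self.z, "p": self.p},
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "z": self.z.tolist(),
            "p": self.p.tolist(),
            "theta": self.theta,
            "sigma_plot": self.sigma_plot,
            "loglik": self.loglik,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Build (y, X, names, group index) from a data frame and a spec."""
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(np.mod(y, 1.0) != 0):
        raise ValueError(f"response '{spec.response}' must be nonnegative integers")
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for c in spec.covariates:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    if spec.year == "numeric" and "year" in data.columns:
        yr = data["year"].to_numpy(dtype=float)
        cols.append(yr - yr.mean())
        names.append("year_c")
    elif spec.year == "factor" and "year" in data.columns:
        levels = sorted(data["year"].unique())
        for lv in levels[1:]:
            cols.append((data["year"] == lv).to_numpy(dtype=float))
            names.append(f"year[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify an aliased column for the error message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"design is rank-deficient: term '{names[j]}' is aliased "
                    "(with year as factor, covariates constant within year "
                    "such as seasonal rainfall are aliased; use year='numeric')"
                )
    groups, gidx = np.unique(data[spec.group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError(f"grouping factor '{spec.group}' has < 2 levels")
    # canonical row order: estimates are then bit-identical no matter how
    # the input rows were ordered
    order = np.lexsort((y, *X.T[::-1], gidx))
    return y[order], X[order], names, gidx[order], len(groups)


def _start_values(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Poisson-GLM start for beta plus a moment estimate of theta."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50)
            beta0 = np.asarray(res.params, dtype=float)
            mu0 = np.asarray(res.mu, dtype=float)
        except Exception:
            beta0 = np.zeros(X.shape[1])
            beta0[0] = np.log(max(y.mean(), 0.1))
            mu0 = np.full_like(y, max(y.mean(), 0.1), dtype=float)
    excess = np.sum((y - mu0) ** 2 - mu0)
    theta0 = np.sum(mu0**2) / excess if excess > 0 else 100.0
    theta0 = float(np.clip(theta0, 0.05, 5e3))
    return np.concatenate([beta0, [np.log(theta0)], [np.log(0.3)]])


def fit_nb_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    fix_sigma_zero: bool = False,
) -> GLMMFit:
    """Fit an NB random-intercept GLMM by marginal maximum likelihood.

    Parameters
    ----------
    data
        One row per observation; must contain the response, covariates,
        the grouping column and (if used) ``year``.
    spec
        Model specification.
    start
        Optional full parameter vector ``(beta, log theta, log sigma)``
        used as a warm start (e.g. from an adjacent scan window).
    fix_sigma_zero
        Constrain sigma to 0, reducing the model to an independent NB
        regression (used for oracle comparisons).
    """
    y, X, names, gidx, n_groups = build_design(data, spec)
    if len(y) < 10:
        raise ValueError(f"need >= 10 observations, got {len(y)}")
    p = X.shape[1]
    cache: dict = {"b": None}

    def negll(params):
        val = marginal_loglik(params, y, X, gidx, n_groups, spec.n_quad, mode_cache=cache)
        return -val if np.isfinite(val) else 1e12

    x0 = _start_values(y, X)
    warm = None
    if start is not None and len(start) == p + 2:
        warm = np.asarray(start, dtype=float).copy()
    pert = x0.copy()
    pert[p] += 1.0
    pert[p + 1] = np.log(0.05)
    # warm start first (cheap); cold starts only if it fails to converge
    starts = [warm, x0, pert] if warm is not None else [x0, pert]
    if fix_sigma_zero:
        for s in starts:
            s[p + 1] = _LOG_SIGMA_ZERO
    sig_hi = _LOG_SIGMA_ZERO if fix_sigma_zero else 2.5
    bounds = [(None, None)] * p + [(-7.0, 13.0), (_LOG_SIGMA_ZERO, sig_hi)]
    opts = {"maxiter": 300, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-6}

    def accept(res):
        # L-BFGS-B reports ABNORMAL when rounding limits further progress;
        # treat it as converged if the projected gradient is small
        g = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        return np.isfinite(res.fun) and (res.success or g < 5e-3)

    best = None
    for s in starts:
        cache["b"] = None
        res = optimize.minimize(negll, s, method="L-BFGS-B", bounds=bounds, options=opts)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if accept(res):
            break  # later starts are fallbacks for non-convergence only
    params = best.x
    beta = params[:p]
    theta = float(np.exp(params[p]))
    sigma = 0.0 if params[p + 1] <= _LOG_SIGMA_ZERO + 1e-9 else float(np.exp(params[p + 1]))
    loglik = -best.fun
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    converged = bool(accept(best))
    if not converged:
        warnings.warn(f"GLMM fit did not converge: {best.message}", stacklevel=2)

    # observed information for beta (theta, sigma held at their estimates)
    se = _beta_se(params, y, X, gidx, n_groups, spec.n_quad)
    z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    mu_pop = np.exp(np.clip(X @ beta, -30.0, 30.0))
    return GLMMFit(
        names=names,
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        theta=theta,
        sigma_plot=sigma,
        loglik=loglik,
        deviance=nb_deviance(y, mu_pop, theta),
        n_obs=len(y),
        n_groups=n_groups,
        converged=converged,
        grad_norm=grad_norm,
        poisson_limit=bool(params[p] >= _LOG_THETA_MAX),
        y=y,
        X=X,
        mu_pop=mu_pop,
    )


def _beta_se(params, y, X, gidx, n_groups, n_quad) -> np.ndarray:
    p = X.shape[1]

    def f(beta):
        q = params.copy()
        q[:p] = beta
        return marginal_loglik(q, y, X, gidx, n_groups, n_quad)

    beta = params[:p]
    hess = np.empty((p, p))
    hstep = 1e-4 * (1.0 + np.abs(beta))
    f0 = f(beta)
    # central second differences
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = hstep[i]
            ej[j] = hstep[j]
            if i == j:
                val = (f(beta + ei) - 2.0 * f0 + f(beta - ei)) / hstep[i] ** 2
            else:
                val = (
                    f(beta + ei + ej) - f(beta + ei - ej) - f(beta - ei + ej) + f(beta - ei - ej)
                ) / (4.0 * hstep[i] * hstep[j])
            hess[i, j] = hess[j, i] = val
    info = -hess
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        return np.sqrt(np.abs(np.diag(cov)))


@dataclass
class R2Report:
    """Deviance-based fixed-effects R^2 with small-sample adjustment."""

    r2: float
    r2_adj: float
    n: int
    p: int
    negative_adjusted: bool = False


def adjusted_r2(fit: GLMMFit, null_fit: GLMMFit) -> R2Report:
    """Fixed-effects R^2 of ``fit`` against its intercept-only null.

    Both deviances are evaluated at population-level fitted means
    (random effect at zero) using the full model's theta; the adjustment
    is Ezekiel's ``1 - (1 - R2) (n-1)/(n-p-1)`` with ``p`` the number of
    non-intercept fixed effects. Since profiles produced by the window
    scan compare the same model family on the same data, any monotone
    variant of this definition yields the same argmax.
    """
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("full and null fits use different data")
    theta = fit.theta
    d_full = nb_deviance(fit.y, fit.mu_pop, theta)
    d_null = nb_deviance(null_fit.y, null_fit.mu_pop, theta)
    if d_null <= 0:
        raise ZeroDivisionError("null deviance is zero; R^2 undefined")
    r2 = 1.0 - d_full / d_null
    n = fit.n_obs
    p = len(fit.beta) - 1
    denom = n - p - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan
    return R2Report(r2=r2, r2_adj=r2_adj, n=n, p=p, negative_adjusted=bool(r2_adj < 0))
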