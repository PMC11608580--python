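"""Binomial GLM / GLMM fitting and likelihood-ratio tests.

Two model families back every inference in the pipeline:

* a binomial GLM with logit link (intercept + one covariate), fitted by
  IRLS through statsmodels, used for the between-dyad association between
  face-looking and verbal mind-mindedness;
* a logistic mixed model with a single normal random intercept per group
  (mother), fitted by maximum likelihood with the marginal likelihood
  approximated per group by a Laplace approximation (default) or adaptive
  Gauss-Hermite quadrature (verification mode), used for the within-dyad
  coincidence analyses.

The GLMM likelihood factorizes over groups, and within a group depends on
the data only through binomial counts per unique covariate value, so the
implementation aggregates observations into (group, x, trials, successes)
cells; with a binary covariate that is two cells per group, which makes
refitting cheap enough for shuffle-null replication at full study scale.
The log-likelihood omits binomial coefficients, i.e. it is the exact
Bernoulli log-likelihood of the disaggregated data, matching what lme4
reports for 0/1 responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, roots_hermite


@dataclass(frozen=True)
class GlmFit:
    """A fitted binomial GLM (logit link)."""

    coefficients: np.ndarray  # log-odds scale, [intercept, slope, ...]
    loglik: float
    converged: bool
    n_obs: int
    n_params: int
    bse: np.ndarray | None = None


@dataclass(frozen=True)
class GlmmFit:
    """A fitted logistic random-intercept model (approximate ML)."""

    fixed_effects: np.ndarray  # log-odds scale, [intercept, slope, ...]
    random_intercept_sd: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    n_params: int  # fixed effects + 1 variance parameter
    method: str = "laplace"


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# GLM


def fit_binomial_glm(successes, trials, x=None) -> GlmFit:
    """ML logit-link binomial regression of successes/trials on x.

    ``x=None`` fits the intercept-only model. The log-likelihood is the
    exact binomial log-likelihood reported by statsmodels (IRLS fit);
    non-convergence or perfect separation yields ``converged=False``.
    """
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if successes.shape != trials.shape:
        raise ValueError("successes and trials must have equal length")
    if np.any(trials < 1) or np.any(successes < 0) or np.any(successes > trials):
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    endog = np.column_stack([successes, trials - successes])
    if x is None:
        exog = np.ones((len(successes), 1))
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        exog = np.column_stack([np.ones(len(x)), x])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            try:
                res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                    maxiter=200, tol=1e-10
                )
            except RuntimeWarning:
                raise sm.tools.sm_exceptions.PerfectSeparationError("separation")
        params = np.asarray(res.params, dtype=float)
        llf = float(res.llf)
        bse = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(params)) or not np.isfinite(llf):
            converged = False
        if np.any(np.abs(params) > 30):
            # logistic coefficients drifting to +-inf: quasi-separation
            converged = False
    except Exception:
        return GlmFit(
            coefficients=np.full(exog.shape[1], np.nan),
            loglik=np.nan,
            converged=False,
            n_obs=len(successes),
            n_params=exog.shape[1],
        )
    return GlmFit(
        coefficients=params,
        loglik=llf,
        converged=converged,
        n_obs=len(successes),
        n_params=exog.shape[1],
        bse=bse,
    )


# ---------------------------------------------------------------------------
# GLMM: cell aggregation


def aggregate_cells(y, group, x=None):
    """Collapse Bernoulli rows to (group, x) binomial cells.

    Returns (cell_group, cell_X, cell_n, cell_k, n_groups, groups) where
    cell_X includes the intercept column.
    """
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary")
    group = np.asarray(group)
    groups, gidx = np.unique(group, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if x is None:
        xv = np.zeros(len(y))
        p = 1
    else:
        xv = np.asarray(x, dtype=float)
        p = 2
    # cell key: (group index, covariate value)
    key = np.stack([gidx.astype(float), xv], axis=1)
    uniq, cidx = np.unique(key, axis=0, return_inverse=True)
    cell_group = uniq[:, 0].astype(int)
    cell_x = uniq[:, 1]
    cell_n = np.bincount(cidx).astype(float)
    cell_k = np.bincount(cidx, weights=y)
    if p == 1:
        cell_X = np.ones((len(cell_n), 1))
    else:
        cell_X = np.column_stack([np.ones(len(cell_n)), cell_x])
    return cell_group, cell_X, cell_n, cell_k, len(groups), groups


def _softplus(v):
    return np.logaddexp(0.0, v)


def _inner_mode(eta0, cell_group, cell_n, cell_k, G, sigma2, tol=1e-11, maxit=60):
    """Per-group Newton maximization of the joint log-density over u.

    The objective per group, q(u) = sum_cells [k*eta - n*softplus(eta)]
    - u^2/(2 sigma^2), is strictly concave, so undamped Newton converges;
    returns (u_hat, p_hat, S1 = sum n p (1-p) per group).
    """
    u = np.zeros(G)
    inv_s2 = 1.0 / sigma2
    for _ in range(maxit):
        eta = eta0 + u[cell_group]
        p = expit(eta)
        g1 = np.bincount(cell_group, weights=cell_k - cell_n * p, minlength=G) - u * inv_s2
        S1 = np.bincount(cell_group, weights=cell_n * p * (1.0 - p), minlength=G)
        step = g1 / (S1 + inv_s2)
        u += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + u[cell_group]
    p = expit(eta)
    S1 = np.bincount(cell_group, weights=cell_n * p * (1.0 - p), minlength=G)
    return u, p, S1


def _laplace_loglik_grad(theta, cell_group, cell_X, cell_n, cell_k, G):
    """Laplace-approximate marginal loglik and its gradient in (beta, sigma)."""
    p_dim = cell_X.shape[1]
    beta = theta[:p_dim]
    sigma = max(float(theta[p_dim]), _SIGMA_FLOOR)
    sigma2 = sigma * sigma
    eta0 = cell_X @ beta
    u, p, S1 = _inner_mode(eta0, cell_group, cell_n, cell_k, G, sigma2)
    eta = eta0 + u[cell_group]
    A = S1 + 1.0 / sigma2

    q = (
        np.bincount(
            cell_group,
            weights=cell_k * eta - cell_n * _softplus(eta),
            minlength=G,
        )
        - u * u / (2.0 * sigma2)
    )
    ll = float(np.sum(q - np.log(sigma) - 0.5 * np.log(A)))

    # gradient (envelope theorem at the inner mode)
    w = cell_n * p * (1.0 - p)
    resid = cell_k - cell_n * p
    S2 = np.bincount(cell_group, weights=w * (1.0 - 2.0 * p), minlength=G)
    grad = np.empty(p_dim + 1)
    for j in range(p_dim):
        xj = cell_X[:, j]
        rj = np.bincount(cell_group, weights=resid * xj, minlength=G)
        S1j = np.bincount(cell_group, weights=w * xj, minlength=G)
        S2j = np.bincount(cell_group, weights=w * (1.0 - 2.0 * p) * xj, minlength=G)
        du = -S1j / A
        dA = S2j + S2 * du
        grad[j] = np.sum(rj - dA / (2.0 * A))
    du_ds = (2.0 * u / sigma**3) / A
    dA_ds = -2.0 / sigma**3 + S2 * du_ds
    grad[p_dim] = np.sum(u * u / sigma**3 - 1.0 / sigma - dA_ds / (2.0 * A))
    return -ll, -grad


def _agq_loglik(theta, cell_group, cell_X, cell_n, cell_k, G, nodes):
    """Adaptive Gauss-Hermite marginal loglik (verification mode)."""
    p_dim = cell_X.shape[1]
    beta = theta[:p_dim]
    sigma = max(float(theta[p_dim]), _SIGMA_FLOOR)
    sigma2 = sigma * sigma
    eta0 = cell_X @ beta
    u, _, S1 = _inner_mode(eta0, cell_group, cell_n, cell_k, G, sigma2)
    A = S1 + 1.0 / sigma2
    s = 1.0 / np.sqrt(A)  # per-group scale

    z, w = roots_hermite(nodes)
    # integral over u per group: sqrt(2)*s * sum_i w_i exp(q(u_hat + sqrt2*s*z_i) + z_i^2)
    logterms = np.empty((nodes, G))
    for i, zi in enumerate(z):
        ui = u + np.sqrt(2.0) * s * zi
        eta = eta0 + ui[cell_group]
        q = (
            np.bincount(
                cell_group,
                weights=cell_k * eta - cell_n * _softplus(eta),
                minlength=G,
            )
            - ui * ui / (2.0 * sigma2)
        )
        logterms[i] = q + zi * zi + np.log(w[i])
    m = logterms.max(axis=0)
    log_integral = m + np.log(np.sum(np.exp(logterms - m), axis=0))
    log_integral += 0.5 * np.log(2.0) + np.log(s)
    ll = float(np.sum(log_integral - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)))
    return -ll


_SIGMA_FLOOR = 1e-6
_SIGMA_CAP = 25.0


def fit_glmm_cells(
    cell_group,
    cell_X,
    cell_n,
    cell_k,
    n_groups: int,
    n_obs: int | None = None,
    method: str = "laplace",
    nodes: int = 15,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Fit the random-intercept logistic model on pre-aggregated cells.

    This is the hot path used by the randomization null; the public
    :func:`fit_binomial_glmm` aggregates raw vectors and delegates here.
    A fit whose variance parameter lands on the lower floor is reported
    with ``random_intercept_sd=0.0`` (the boundary is a valid estimate).
    """
    p_dim = cell_X.shape[1]
    if n_obs is None:
        n_obs = int(np.sum(cell_n))
    if start is None:
        # pooled logistic start: one or two Newton steps on aggregate data
        beta0 = np.zeros(p_dim)
        beta0[0] = _safe_logit(np.sum(cell_k) / np.sum(cell_n))
        start = np.concatenate([beta0, [0.5]])
    else:
        start = np.asarray(start, dtype=float).copy()
        start[p_dim] = np.clip(start[p_dim], 2 * _SIGMA_FLOOR, _SIGMA_CAP / 2)

    args = (np.asarray(cell_group), np.asarray(cell_X, dtype=float),
            np.asarray(cell_n, dtype=float), np.asarray(cell_k, dtype=float),
            n_groups)
    bounds = [(None, None)] * p_dim + [(_SIGMA_FLOOR, _SIGMA_CAP)]
    res = optimize.minimize(
        _laplace_loglik_grad,
        start,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    ll = -float(res.fun)
    converged = bool(res.success) and np.all(np.isfinite(theta)) and np.isfinite(ll)
    if not converged and np.all(np.isfinite(theta)) and np.isfinite(ll):
        # L-BFGS-B line searches can terminate "abnormally" at the optimum
        # from rounding in the inner mode; accept if the projected gradient
        # is negligible (sigma component ignored when pinned at the floor).
        _, grad = _laplace_loglik_grad(theta, *args)
        pg = grad.copy()
        if theta[p_dim] <= 2 * _SIGMA_FLOOR and pg[p_dim] > 0:
            pg[p_dim] = 0.0
        converged = bool(np.max(np.abs(pg)) < 1e-2)
    if method == "agq":
        # re-optimize the quadrature objective from the Laplace solution
        res2 = optimize.minimize(
            _agq_loglik,
            theta,
            args=args + (nodes,),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        theta = res2.x
        ll = -float(res2.fun)
        converged = converged and bool(res2.success)
    sigma = float(theta[p_dim])
    if sigma <= 5 * _SIGMA_FLOOR:
        sigma = 0.0
    return GlmmFit(
        fixed_effects=np.asarray(theta[:p_dim], dtype=float),
        random_intercept_sd=sigma,
        loglik=ll,
        converged=converged,
        n_obs=n_obs,
        n_groups=n_groups,
        n_params=p_dim + 1,
        method=method,
    )


def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-10), 1 - 1e-10)
    return float(np.log(p / (1 - p)))


def fit_binomial_glmm(
    y,
    group,
    x=None,
    method: str = "laplace",
    nodes: int = 15,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Logistic regression of binary y on x with a random intercept per group.

    ``x=None`` fits the null (intercept + random intercept) model. The
    reported log-likelihood is the approximate marginal Bernoulli
    log-likelihood (Laplace by default; ``method='agq'`` uses adaptive
    Gauss-Hermite quadrature with ``nodes`` points, at least 9 recommended).
    """
    if method == "agq" and nodes < 2:
        raise ValueError("quadrature needs at least 2 nodes")
    cg, cX, cn, ck, G, _ = aggregate_cells(y, group, x)
    return fit_glmm_cells(
        cg, cX, cn, ck, G, n_obs=len(np.asarray(y)), method=method,
        nodes=nodes, start=start,
    )


def glmm_loglik(fit: GlmmFit, y, group, x=None, method=None, nodes: int = 15) -> float:
    """Evaluate the (approximate) marginal loglik of a fit on given data."""
    cg, cX, cn, ck, G, _ = aggregate_cells(y, group, x)
    theta = np.concatenate(
        [fit.fixed_effects, [max(fit.random_intercept_sd, _SIGMA_FLOOR)]]
    )
    args = (cg, cX, cn, ck, G)
    if (method or fit.method) == "agq":
        return -_agq_loglik(theta, *args, nodes)
    return -_laplace_loglik_grad(theta, *args)[0]


# ---------------------------------------------------------------------------
# LRT


def lrt(full: GlmFit | GlmmFit, null: GlmFit | GlmmFit) -> LrtResult:
    """Likelihood-ratio test of nested fits: chi2 = 2 (ll_full - ll_null)."""
    if not (full.converged and null.converged):
        raise ValueError("LRT requires both fits to have converged")
    df = full.n_params - null.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than the null")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LrtResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))
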