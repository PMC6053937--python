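"""Maximum-likelihood random-intercept GLMMs via Gauss–Hermite quadrature.

Fits models of the form

    g(E[y_ij | u_i]) = x_ij' beta + u_i,   u_i ~ N(0, sigma^2)

for a binomial (logit link) or negative-binomial (log link, NB2) response,
by direct maximisation of the marginal likelihood.  The integral over each
group's random intercept is approximated with Gauss–Hermite quadrature
(default 25 nodes), which is accurate for the modest intercept variances
typical of behavioural response data; the gradient is computed analytically
and standard errors come from the numerically differentiated observed
information at the optimum.

This is deliberately small: one scalar random intercept, no crossed or
nested effects, no correlated slopes.  Gaussian mixed models are better
served by ``statsmodels`` MixedLM (see ``alarmnet.models``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = ["GLMMResult", "fit_binomial_glmm", "fit_negbin_glmm"]

_MAX_EXP = 30.0


@dataclass
class GLMMResult:
    """ML fit of a random-intercept GLMM.

    ``params``/``se`` cover the fixed effects in column order; ``sigma`` is
    the random-intercept SD and ``alpha`` the NB2 dispersion (None for
    binomial).  ``loglik`` is the marginal log-likelihood and ``k`` the
    total parameter count used for information criteria.
    """

    params: np.ndarray
    se: np.ndarray
    sigma: float
    sigma_se: float
    alpha: float | None
    loglik: float
    k: int
    n: int
    converged: bool
    cov: np.ndarray


def _group_index(groups):
    uniq, inv = np.unique(np.asarray(groups), return_inverse=True)
    return uniq, inv


def _binomial_ll_parts(eta, y):
    # log f(y | eta) for Bernoulli-logit, elementwise; clipped for stability
    eta = np.clip(eta, -_MAX_EXP, _MAX_EXP)
    return y * eta - np.log1p(np.exp(eta))


def _binomial_resid(eta, y):
    return y - expit(np.clip(eta, -_MAX_EXP, _MAX_EXP))


def _make_negbin_parts(alpha):
    def ll(eta, y):
        mu = np.exp(np.clip(eta, -_MAX_EXP, _MAX_EXP))
        inv = 1.0 / alpha
        return (gammaln(y + inv) - gammaln(inv) - gammaln(y + 1.0)
                + inv * np.log(inv) + y * np.log(mu)
                - (y + inv) * np.log(inv + mu))

    def resid(eta, y):
        mu = np.exp(np.clip(eta, -_MAX_EXP, _MAX_EXP))
        inv = 1.0 / alpha
        return y - (y + inv) * mu / (inv + mu)

    return ll, resid


def _marginal_loglik_grad(beta, sigma, X, y, inv_grp, n_groups, nodes, wts,
                          ll_fn, resid_fn, extra_grad=None):
    """Marginal log-likelihood and gradient wrt (beta, sigma[, extra])."""
    eta0 = X @ beta
    G, K = n_groups, len(nodes)
    # per-node group log-likelihoods: (G, K)
    glp = np.empty((G, K))
    for k in range(K):
        lp = ll_fn(eta0 + sigma * nodes[k], y)
        glp[:, k] = np.bincount(inv_grp, weights=lp, minlength=G)
    glp_w = glp + np.log(wts)[None, :]
    m = glp_w.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(glp_w - m).sum(axis=1))
    post = np.exp(glp_w - lse[:, None])               # (G, K) posterior node wts

    obs_w = np.zeros(len(y))
    g_beta = np.zeros(len(beta))
    g_sigma = 0.0
    for k in range(K):
        r = resid_fn(eta0 + sigma * nodes[k], y)
        w = post[inv_grp, k]
        g_beta += X.T @ (w * r)
        g_sigma += nodes[k] * np.sum(w * r)
    return lse.sum(), g_beta, g_sigma, post


def _fit(X, y, groups, ll_resid_factory, n_quad, start, extra_param, maxiter):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    uniq, inv = _group_index(groups)
    G = len(uniq)
    z, w = hermegauss(n_quad)                 # probabilists': weights sum sqrt(2 pi)
    w = w / np.sqrt(2.0 * np.pi)

    def unpack(theta):
        # the likelihood is even in sigma, so it is left unconstrained and
        # reported as |sigma|
        beta = theta[:p]
        sigma = theta[p]
        extra = np.exp(theta[p + 1]) if extra_param else None
        return beta, sigma, extra

    def negloglik(theta):
        beta, sigma, extra = unpack(theta)
        ll_fn, resid_fn = ll_resid_factory(extra)
        ll, *_ = _marginal_loglik_grad(beta, sigma, X, y, inv, G, z, w,
                                       ll_fn, resid_fn)
        return -ll

    def grad(theta):
        beta, sigma, extra = unpack(theta)
        ll_fn, resid_fn = ll_resid_factory(extra)
        _, gb, gs, _ = _marginal_loglik_grad(beta, sigma, X, y, inv, G, z, w,
                                             ll_fn, resid_fn)
        g = np.empty_like(theta)
        g[:p] = -gb
        g[p] = -gs
        if extra_param:
            eps = 1e-5
            tp, tm = theta.copy(), theta.copy()
            tp[p + 1] += eps
            tm[p + 1] -= eps
            g[p + 1] = (negloglik(tp) - negloglik(tm)) / (2 * eps)
        return g

    res = minimize(negloglik, start, jac=grad, method="BFGS",
                   options={"maxiter": maxiter, "gtol": 1e-6})
    theta = res.x
    beta, sigma, extra = unpack(theta)
    H = _numeric_hessian(negloglik, theta)
    cov = _robust_inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    k = p + 1 + (1 if extra_param else 0)
    return GLMMResult(
        params=beta, se=se[:p], sigma=abs(sigma), sigma_se=se[p],
        alpha=extra, loglik=-res.fun, k=k, n=n,
        converged=bool(res.success or res.status == 2), cov=cov,
    )


def _numeric_hessian(f, x, eps=1e-4):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    for i in range(d):
        xi = x.copy()
        xi[i] += eps
        fp[i] = f(xi)
    for i in range(d):
        for j in range(i, d):
            xij = x.copy()
            xij[i] += eps
            xij[j] += eps
            H[i, j] = H[j, i] = (f(xij) - fp[i] - fp[j] + f0) / eps**2
    return H


def _robust_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_binomial_glmm(X, y, groups, n_quad: int = 25, start_beta=None,
                      maxiter: int = 200) -> GLMMResult:
    """Bernoulli-logit random-intercept GLMM by GH-quadrature ML.

    ``X`` must include an intercept column if one is wanted.  ``start_beta``
    (e.g. a plain logistic fit) speeds convergence.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    start = np.zeros(p + 1)
    if start_beta is not None:
        start[:p] = start_beta
    start[p] = 0.3

    def factory(_extra):
        return _binomial_ll_parts, _binomial_resid

    return _fit(X, y, groups, factory, n_quad, start, extra_param=False,
                maxiter=maxiter)


def fit_negbin_glmm(X, y, groups, n_quad: int = 25, start_beta=None,
                    start_alpha: float = 0.5, maxiter: int = 200) -> GLMMResult:
    """NB2 log-link random-intercept GLMM; dispersion alpha estimated by ML."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    start = np.zeros(p + 2)
    if start_beta is not None:
        start[:p] = start_beta
    else:
        ybar = max(np.asarray(y, dtype=float).mean(), 0.1)
        start[0] = np.log(ybar)
    start[p] = 0.3
    start[p + 1] = np.log(start_alpha)

    return _fit(X, y, groups, lambda a: _make_negbin_parts(a), n_quad, start,
                extra_param=True, maxiter=maxiter)
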