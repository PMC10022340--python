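"""Maximum-likelihood left-truncated normal regression.

The second-stage model of the two-stage efficiency analysis: the output
distance delta of a unit is assumed to follow

    delta_i = z_i' beta + eps_i,   eps_i ~ N(0, sigma^2),

observed only where delta_i >= a (here a = 1, since a distance below one is
impossible).  The log-likelihood of one observation is

    log phi((delta_i - z_i'beta)/sigma) - log sigma
        - log Phi((z_i'beta - a)/sigma),

maximised over (beta, log sigma) by quasi-Newton with the analytic score,
started from ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr, ndtri

from .exceptions import DomainError

__all__ = ["TruncRegFit", "fit_truncated_regression", "draw_truncated_normal"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class TruncRegFit:
    beta: np.ndarray
    sigma: float
    loglik: float
    gradient_norm: float
    converged: bool
    n_used: int

    @property
    def params(self) -> np.ndarray:
        return np.append(self.beta, self.sigma)


def _inverse_mills(h: np.ndarray) -> np.ndarray:
    """phi(h) / Phi(h), computed in log space for stability at h << 0."""
    return np.exp(-0.5 * h * h - _LOG_SQRT_2PI - log_ndtr(h))


def _negloglik_and_grad(theta, delta, Z, a):
    p = Z.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[p])
    mu = Z @ beta
    r = (delta - mu) / sigma
    h = (mu - a) / sigma
    ll = -0.5 * r * r - _LOG_SQRT_2PI - theta[p] - log_ndtr(h)
    lam = _inverse_mills(h)
    # d ll / d mu = r/sigma - lam/sigma ; d ll / d log sigma = r^2 - 1 + h*lam
    g_beta = Z.T @ ((r - lam) / sigma)
    g_logsigma = np.sum(r * r - 1.0 + h * lam)
    grad = np.append(g_beta, g_logsigma)
    return -np.sum(ll), -grad


def fit_truncated_regression(
    delta: np.ndarray,
    Z: np.ndarray,
    truncation_point: float = 1.0,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> TruncRegFit:
    """Fit the left-truncated normal regression of ``delta`` on ``Z``.

    Parameters
    ----------
    delta : response vector, every entry >= ``truncation_point``.
    Z : design matrix including the intercept column.
    truncation_point : left truncation bound on the response scale.
    start : optional warm start ``(beta..., sigma)``; defaults to OLS.

    Returns
    -------
    TruncRegFit with ``beta`` (intercept first), ``sigma``, the maximised
    log-likelihood and the score norm at the optimum.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, p = Z.shape
    if delta.shape[0] != n:
        raise DomainError("delta and Z have mismatched lengths")
    if np.any(delta < truncation_point - 1e-12):
        raise DomainError(
            "all responses must lie at or above the truncation point"
        )
    if n <= p + 1:
        raise DomainError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(Z) < p:
        raise DomainError("design matrix is rank deficient")

    if start is not None:
        theta0 = np.append(start[:p], np.log(max(start[p], 1e-8)))
    else:
        beta0, *_ = np.linalg.lstsq(Z, delta, rcond=None)
        resid = delta - Z @ beta0
        s0 = max(np.std(resid, ddof=p), 1e-3)
        theta0 = np.append(beta0, np.log(s0))

    res = minimize(
        _negloglik_and_grad,
        theta0,
        args=(delta, Z, truncation_point),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta, nll, grad = res.x, res.fun, res.jac
    gnorm = float(np.max(np.abs(grad)))
    if gnorm > 1e-7:
        theta, nll, grad = _newton_polish(theta, nll, grad,
                                          (delta, Z, truncation_point))
        gnorm = float(np.max(np.abs(grad)))
    beta = theta[:p]
    sigma = float(np.exp(theta[p]))
    return TruncRegFit(
        beta=beta,
        sigma=sigma,
        loglik=float(-nll),
        gradient_norm=gnorm,
        converged=gnorm <= 1e-4,
        n_used=n,
    )


def _newton_polish(theta, nll, grad, args, max_steps: int = 20):
    """Damped Newton steps (finite-difference Hessian of the score) to
    drive the gradient norm to solver precision after quasi-Newton exits."""
    k = len(theta)
    for _ in range(max_steps):
        if np.max(np.abs(grad)) <= 1e-8:
            break
        H = np.empty((k, k))
        h = 1e-6 * np.maximum(1.0, np.abs(theta))
        for j in range(k):
            e = np.zeros(k)
            e[j] = h[j]
            gp = _negloglik_and_grad(theta + e, *args)[1]
            gm = _negloglik_and_grad(theta - e, *args)[1]
            H[:, j] = (gp - gm) / (2 * h[j])
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(k), -grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        while t > 1e-6:
            cand = theta + t * step
            nll_c, grad_c = _negloglik_and_grad(cand, *args)
            if np.isfinite(nll_c) and (
                    nll_c < nll
                    or np.max(np.abs(grad_c)) < np.max(np.abs(grad))):
                theta, nll, grad = cand, nll_c, grad_c
                break
            t *= 0.5
        else:
            break
    return theta, nll, grad


def loglik(beta, sigma, delta, Z, truncation_point=1.0) -> float:
    """Log-likelihood at arbitrary parameters (used by tests and oracles)."""
    theta = np.append(beta, np.log(sigma))
    nll, _ = _negloglik_and_grad(theta, np.asarray(delta, float),
                                 np.atleast_2d(np.asarray(Z, float)),
                                 truncation_point)
    return -nll


def draw_truncated_normal(mean, sigma, lower, rng) -> np.ndarray:
    """Draws from N(mean, sigma^2) conditioned on the value being >= lower.

    Vectorised over ``mean`` (and ``lower``).  Uses the inverse-CDF method on
    the upper-tail probability, which is stable far into the tail; when the
    tail mass underflows entirely, falls back to an exponential-proposal
    rejection sampler (Robert, 1995).

    Parameters
    ----------
    mean, lower : scalars or arrays (broadcast together).
    sigma : positive scalar.
    rng : numpy Generator.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    mean = np.asarray(mean, dtype=float)
    scalar = mean.ndim == 0
    mean = np.atleast_1d(mean)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), mean.shape)
    with np.errstate(over="ignore"):  # inf alpha handled as degenerate below
        alpha = (lower - mean) / sigma
    # upper-tail mass above the truncation point
    p_tail = ndtr(-alpha)
    u = rng.uniform(size=mean.shape)
    out = np.empty_like(mean)
    ok = p_tail > 1e-300
    # target upper-tail probability p_tail*(1-u); invert the survival function
    out[ok] = mean[ok] - sigma * ndtri(p_tail[ok] * (1.0 - u[ok]))
    if np.any(~ok):
        # mass numerically exhausted: the conditional law degenerates to the
        # boundary beyond ~1e8 sigma; otherwise rejection-sample the tail
        for i in np.nonzero(~ok)[0]:
            if alpha[i] > 1e8:
                out[i] = lower[i]
            else:
                out[i] = mean[i] + sigma * _tail_rejection(alpha[i], rng)
    out = np.maximum(out, lower)  # guard against roundoff at the boundary
    return float(out[0]) if scalar else out


def _tail_rejection(alpha: float, rng) -> float:
    """Standard-normal draw conditioned on >= alpha, for extreme alpha > 0."""
    # exponential proposal with optimal rate (alpha + sqrt(alpha^2+4))/2
    rate = 0.5 * (alpha + np.sqrt(alpha * alpha + 4.0))
    while True:
        e = rng.exponential(1.0 / rate)
        z = alpha + e
        if rng.uniform() <= np.exp(-0.5 * (z - rate) ** 2):
            return z
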