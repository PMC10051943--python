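"""Shared approximate-inference utilities.

All Bayesian model fits in this package go through :func:`fit_map_laplace`:
the posterior mode is located with quasi-Newton optimisation on an
unconstrained parameterisation and the posterior is approximated by a
Gaussian centred at the mode with covariance equal to the inverse Hessian
of the negative log posterior (Laplace approximation).  Models that want an
asymptotically exact alternative can run the same log-posterior through
emcee (see :meth:`affectdyn.ou.OUModel.fit`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "LaplaceFit",
    "fit_map_laplace",
    "hdi",
    "truncnorm_logpdf",
    "truncnorm_mean",
    "truncnorm_rvs",
]


@dataclass
class LaplaceFit:
    """MAP estimate plus Gaussian posterior approximation."""

    x_map: np.ndarray
    cov: np.ndarray
    draws: np.ndarray  # (n_draws, dim), in the unconstrained space
    logpost_at_map: float
    diagnostics: dict = field(default_factory=dict)


def _fd_gradient(f, x, h=1e-6):
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        step = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2 * step)
    return g


def _fd_hessian_from_grad(grad, x, h=1e-5):
    x = np.asarray(x, float)
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        step = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (grad(xp) - grad(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def _fd_hessian_from_values(f, x, h=1e-4):
    x = np.asarray(x, float)
    n = x.size
    steps = h * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit_map_laplace(
    neg_logpost,
    x0,
    grad=None,
    n_draws=1000,
    seed=0,
    maxiter=500,
    bounds=None,
):
    """Locate the posterior mode and draw from the Laplace approximation.

    Parameters
    ----------
    neg_logpost : callable
        Negative log posterior on the unconstrained space.
    x0 : array_like
        Starting point.
    grad : callable, optional
        Analytic gradient of ``neg_logpost``; finite differences otherwise.
    n_draws : int
        Number of Gaussian posterior draws to return.
    seed : int or numpy Generator
        Source of randomness for the draws.
    """
    x0 = np.asarray(x0, float)
    res = optimize.minimize(
        neg_logpost,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter * max(1, x0.size)},
    )
    x_map = res.x

    if grad is not None:
        H = _fd_hessian_from_grad(grad, x_map)
    else:
        H = _fd_hessian_from_values(neg_logpost, x_map)

    evals, evecs = np.linalg.eigh(H)
    floor = max(evals.max(), 1.0) * 1e-10
    pd = bool(evals.min() > 0)
    evals = np.clip(evals, floor, None)
    cov = (evecs / evals) @ evecs.T

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, x_map.size))
    draws = x_map + (z / np.sqrt(evals)) @ evecs.T

    diagnostics = {
        "converged": bool(res.success),
        "message": str(res.message),
        "n_iter": int(res.nit),
        "hessian_pd": pd,
        "min_hessian_eig": float(np.linalg.eigvalsh(H).min()),
    }
    if not res.success:
        warnings.warn(f"MAP optimisation did not report convergence: {res.message}")
    return LaplaceFit(x_map, cov, draws, float(-res.fun), diagnostics)


def hdi(draws, mass=0.95):
    """Narrowest interval containing ``ceil(mass * M)`` of the sorted draws.

    Permutation-invariant in its input; for a flat sample every candidate
    window has the same width and the left-most is returned.
    """
    x = np.sort(np.asarray(draws, float).ravel())
    m = x.size
    if m == 0:
        raise ValueError("hdi of an empty sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * m))
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _log_z(alpha, beta):
    """log(Phi(beta) - Phi(alpha)) computed in the better tail."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    # Work in the left tail of whichever side is numerically safer.
    flip = alpha + beta > 0
    a = np.where(flip, -beta, alpha)
    b = np.where(flip, -alpha, beta)
    lb = special.log_ndtr(b)
    la = special.log_ndtr(a)
    with np.errstate(invalid="ignore"):
        out = lb + np.log1p(-np.exp(la - lb))
    return out


def truncnorm_logpdf(x, mu, sigma, lo=1.0, hi=7.0):
    """Log density of a Normal(mu, sigma^2) truncated to [lo, hi]."""
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    z = (x - mu) / sigma
    alpha = (lo - mu) / sigma
    beta = (hi - mu) / sigma
    core = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma) - _log_z(alpha, beta)
    return np.where((x < lo) | (x > hi), -np.inf, core)


def truncnorm_mean(mu, sigma, lo=1.0, hi=7.0):
    """Mean of a Normal(mu, sigma^2) truncated to [lo, hi]."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    alpha = (lo - mu) / sigma
    beta = (hi - mu) / sigma
    log_z = _log_z(alpha, beta)
    lphi_a = -0.5 * alpha**2 - 0.5 * np.log(2 * np.pi)
    lphi_b = -0.5 * beta**2 - 0.5 * np.log(2 * np.pi)
    return mu + sigma * (np.exp(lphi_a - log_z) - np.exp(lphi_b - log_z))


def truncnorm_rvs(rng, mu, sigma, lo=1.0, hi=7.0, size=None):
    """Draw from a Normal(mu, sigma^2) truncated to [lo, hi]."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
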