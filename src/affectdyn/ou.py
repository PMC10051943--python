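"""Ornstein-Uhlenbeck state-space model of core affect.

A subject's continuously annotated valence/arousal trajectory is modelled as
a latent two-dimensional OU process observed through additive Gaussian
noise::

    dS_t = B (U - S_t) dt + D^{1/2} dW_t
    Y_t  = S_t + R^{1/2} eps_t

``U`` is the affective home base (the attractor the state is pulled
towards), ``B`` the symmetric dampening-force matrix (all eigenvalues
positive), ``D`` the diffusion covariance of the driving noise and ``R`` a
diagonal observation-noise covariance.  Axis order is (arousal, valence)
throughout, matching the descriptor ordering
``[U_A, U_V, B_AA, B_AV, B_VV, D_AA, D_AV, D_VV]``.

The default transition likelihood applies the Euler-Maruyama kernel
directly to the observed trajectory (treating Y as the Markov state); exact
marginalisation of the latent state, which accounts for R, is available as
the opt-in ``"kalman"`` kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_continuous_lyapunov

from ._bayes import fit_map_laplace, hdi

__all__ = [
    "DESCRIPTOR_LABELS",
    "Trajectory",
    "OUParams",
    "simulate",
    "log_likelihood",
    "OUModel",
    "OUResults",
]

DESCRIPTOR_LABELS = ("U_A", "U_V", "B_AA", "B_AV", "B_VV", "D_AA", "D_AV", "D_VV")

#: unconstrained parameter vector layout used by the fitter
_PARAM_NAMES = (
    "U_A", "U_V", "log_B_AA", "log_B_VV", "arctanh_rho_B",
    "log_d_A", "log_d_V", "arctanh_rho_D", "log_r_A", "log_r_V",
)


@dataclass
class Trajectory:
    """Uniformly sampled 2-D (arousal, valence) time series."""

    t: np.ndarray
    y: np.ndarray  # (N, 2), columns (arousal, valence)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if self.y.ndim != 2 or self.y.shape[1] != 2:
            raise ValueError("y must be (N, 2) with columns (arousal, valence)")
        if self.t.shape != (self.y.shape[0],):
            raise ValueError("t and y lengths differ")
        if len(self.t) < 3:
            raise ValueError("trajectory needs at least 3 samples")
        steps = np.diff(self.t)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("t must be a strictly increasing uniform grid")
        if not (np.isfinite(self.t).all() and np.isfinite(self.y).all()):
            raise ValueError("trajectory contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def arousal(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def valence(self) -> np.ndarray:
        return self.y[:, 1]

    def plot(self, ax=None, **kwargs):
        """Plot the trajectory in the valence/arousal plane."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.valence, self.arousal, **kwargs)
        ax.set_xlabel("valence")
        ax.set_ylabel("arousal")
        return ax


def _psd_sqrt(a):
    """Symmetric square root of a PSD matrix (eigenvalues clipped at 0)."""
    vals, vecs = np.linalg.eigh(np.asarray(a, float))
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


@dataclass
class OUParams:
    """Parameters Theta = {U, B, D, R} of the OU state-space model."""

    U: np.ndarray          # (2,) home base, (arousal, valence)
    B: np.ndarray          # (2, 2) symmetric, positive eigenvalues
    D: np.ndarray          # (2, 2) symmetric positive semi-definite
    R: np.ndarray = None   # (2, 2) diagonal non-negative observation noise
    validate: bool = True

    def __post_init__(self):
        self.U = np.asarray(self.U, float).reshape(2)
        self.B = np.asarray(self.B, float).reshape(2, 2)
        self.D = np.asarray(self.D, float).reshape(2, 2)
        self.R = (
            np.zeros((2, 2)) if self.R is None else np.asarray(self.R, float).reshape(2, 2)
        )
        if self.validate:
            if not np.allclose(self.B, self.B.T):
                raise ValueError("B must be symmetric")
            if np.linalg.eigvalsh(self.B).min() <= 0:
                raise ValueError("B must have positive eigenvalues")
            if not np.allclose(self.D, self.D.T):
                raise ValueError("D must be symmetric")
            if np.linalg.eigvalsh(self.D).min() < -1e-12:
                raise ValueError("D must be positive semi-definite")
            if not np.allclose(self.R, np.diag(np.diag(self.R))):
                raise ValueError("R must be diagonal")
            if np.diag(self.R).min() < 0:
                raise ValueError("R must be non-negative")

    @classmethod
    def from_natural(cls, u, b_diag, rho_b, d_scales, rho_d, r_scales=(0.0, 0.0)):
        """Build from the constrained parameterisation used by the fitter.

        ``B`` has diagonal ``b_diag`` and off-diagonal
        ``rho_b * sqrt(B_AA * B_VV)`` (|rho_b| < 1 guarantees positive
        eigenvalues for positive diagonals); ``D = S C S`` with scale vector
        ``d_scales`` and correlation ``rho_d``; ``R = diag(r_scales)**2``.
        """
        b_aa, b_vv = b_diag
        B = np.array(
            [[b_aa, rho_b * np.sqrt(b_aa * b_vv)], [rho_b * np.sqrt(b_aa * b_vv), b_vv]]
        )
        dA, dV = d_scales
        D = np.array([[dA**2, rho_d * dA * dV], [rho_d * dA * dV, dV**2]])
        R = np.diag(np.square(r_scales))
        return cls(np.asarray(u, float), B, D, R)

    @property
    def descriptor(self) -> np.ndarray:
        """8-vector [U_A, U_V, B_AA, B_AV, B_VV, D_AA, D_AV, D_VV]."""
        return np.array(
            [
                self.U[0], self.U[1],
                self.B[0, 0], self.B[0, 1], self.B[1, 1],
                self.D[0, 0], self.D[0, 1], self.D[1, 1],
            ]
        )

    def stationary_cov(self) -> np.ndarray:
        """Lyapunov solution Sigma of B Sigma + Sigma B' = D."""
        return solve_continuous_lyapunov(self.B, self.D)


def simulate(params, n_steps, dt, s0=None, seed=0):
    """Sample one trajectory by Euler-Maruyama discretisation.

    The latent state iterates
    ``S_{t+dt} = S_t + B (U - S_t) dt + sqrt(dt) D^{1/2} eps`` and each
    observation is ``Y_t = S_t + R^{1/2} eps``.  ``s0`` defaults to the
    home base U.  Raises if the deterministic map ``I - B dt`` is unstable
    (spectral radius >= 1), i.e. the step is too coarse for the dynamics.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = np.eye(2) - params.B * dt
    if np.abs(np.linalg.eigvals(A)).max() >= 1.0:
        raise ValueError(
            "Euler step unstable: spectral radius of (I - B dt) >= 1; reduce dt"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sqrt_D = _psd_sqrt(params.D)
    sqrt_R = _psd_sqrt(params.R)
    s = np.asarray(params.U if s0 is None else s0, float).copy()
    S = np.empty((n_steps, 2))
    eps_s = rng.standard_normal((n_steps, 2))
    eps_y = rng.standard_normal((n_steps, 2))
    sq_dt = np.sqrt(dt)
    for k in range(n_steps):
        S[k] = s
        s = s + params.B @ (params.U - s) * dt + sq_dt * (sqrt_D @ eps_s[k])
    Y = S + eps_y @ sqrt_R.T
    return Trajectory(t=np.arange(n_steps) * dt, y=Y)


def _euler_loglik(traj, params):
    y = traj.y
    dt = traj.dt
    cov = params.D * dt
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular transition covariance D*dt")
    prec = np.linalg.inv(cov)
    resid = y[1:] - y[:-1] - (params.U - y[:-1]) @ params.B.T * dt
    quad = np.einsum("ni,ij,nj->n", resid, prec, resid)
    n_tr = len(resid)
    return float(-0.5 * (quad.sum() + n_tr * (logdet + 2 * np.log(2 * np.pi))))


def _kalman_loglik(traj, params):
    """Exact likelihood of the linear-Gaussian SSM, latent state marginalised.

    The initial state is given the stationary OU distribution
    N(U, Sigma_stationary).
    """
    y = traj.y
    dt = traj.dt
    A = np.eye(2) - params.B * dt
    c = params.B @ params.U * dt
    Q = params.D * dt
    Robs = params.R
    m = params.U.copy()
    P = params.stationary_cov()
    ll = 0.0
    for k in range(traj.n):
        S = P + Robs
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular innovation covariance")
        Sinv = np.linalg.inv(S)
        innov = y[k] - m
        ll += -0.5 * (innov @ Sinv @ innov + logdet + 2 * np.log(2 * np.pi))
        K = P @ Sinv
        m = m + K @ innov
        P = P - K @ P
        m = A @ m + c
        P = A @ P @ A.T + Q
    return float(ll)


def log_likelihood(traj, params, kernel="euler"):
    """Log likelihood of a trajectory under Theta.

    ``kernel="euler"`` (default): product of Euler-Maruyama Gaussian
    transition densities applied directly to the observations, with mean
    ``Y_t + B (U - Y_t) dt`` and covariance ``D dt``.  ``kernel="kalman"``:
    exact marginalisation of the latent state including R.
    """
    if kernel == "euler":
        return _euler_loglik(traj, params)
    if kernel == "kalman":
        return _kalman_loglik(traj, params)
    raise ValueError(f"unknown kernel {kernel!r}")


# --- unconstrained parameter vector <-> constrained quantities -------------

def _unpack(x):
    uA, uV, lbA, lbV, arB, ldA, ldV, arD, lrA, lrV = x
    return OUParams.from_natural(
        (uA, uV),
        (np.exp(lbA), np.exp(lbV)),
        np.tanh(arB),
        (np.exp(ldA), np.exp(ldV)),
        np.tanh(arD),
        (np.exp(lrA), np.exp(lrV)),
    )


def _draws_frame(X):
    """Map unconstrained draw matrix to named constrained quantities."""
    bAA, bVV = np.exp(X[:, 2]), np.exp(X[:, 3])
    rhoB = np.tanh(X[:, 4])
    dA, dV = np.exp(X[:, 5]), np.exp(X[:, 6])
    rhoD = np.tanh(X[:, 7])
    return pd.DataFrame(
        {
            "U_A": X[:, 0],
            "U_V": X[:, 1],
            "B_AA": bAA,
            "B_AV": rhoB * np.sqrt(bAA * bVV),
            "B_VV": bVV,
            "D_AA": dA**2,
            "D_AV": rhoD * dA * dV,
            "D_VV": dV**2,
            "rho_B": rhoB,
            "rho_D": rhoD,
            "R_A": np.exp(2 * X[:, 8]),
            "R_V": np.exp(2 * X[:, 9]),
        }
    )


_DEFAULT_PRIORS = {
    "u_sd": 1.0,        # U ~ N(0, 1) per dimension
    "log_b_sd": 1.0,    # B_AA, B_VV ~ LogNormal(0, 1)
    "d_scale": 1.0,     # D scales ~ HalfNormal(1)
    "r_scale": 0.1,     # R scales ~ HalfNormal(0.1)
    # rho_B, rho_D ~ Uniform(-1, 1)
}


def _log_prior(x, priors):
    uA, uV, lbA, lbV, arB, ldA, ldV, arD, lrA, lrV = x
    lp = -0.5 * (uA**2 + uV**2) / priors["u_sd"] ** 2
    lp += -0.5 * (lbA**2 + lbV**2) / priors["log_b_sd"] ** 2
    # Uniform(-1, 1) correlations through arctanh: Jacobian log(1 - rho^2)
    for a in (arB, arD):
        lp += np.log1p(-np.tanh(a) ** 2)
    for ld in (ldA, ldV):
        d = np.exp(ld)
        lp += -0.5 * d**2 / priors["d_scale"] ** 2 + ld
    for lr in (lrA, lrV):
        r = np.exp(lr)
        lp += -0.5 * r**2 / priors["r_scale"] ** 2 + lr
    return lp


class OUModel:
    """Bayesian OU state-space model for one observed trajectory.

    Parameters
    ----------
    traj : Trajectory
        The observed (fused) valence/arousal trajectory.
    priors : dict, optional
        Overrides for the default prior scales (keys ``u_sd``, ``log_b_sd``,
        ``d_scale``, ``r_scale``).
    kernel : {"euler", "kalman"}
        Transition likelihood; see :func:`log_likelihood`.
    """

    def __init__(self, traj, priors=None, kernel="euler"):
        self.traj = traj
        self.priors = dict(_DEFAULT_PRIORS, **(priors or {}))
        self.kernel = kernel

    # moment-matched starting point: OLS of increments on (U - y)
    def _init_point(self):
        y = self.traj.y
        dt = self.traj.dt
        u0 = y.mean(axis=0)
        X = u0 - y[:-1]
        dy = np.diff(y, axis=0)
        Bt, *_ = np.linalg.lstsq(X * dt, dy, rcond=None)
        B0 = 0.5 * (Bt.T + Bt)
        resid = dy - X @ B0.T * dt
        D0 = resid.T @ resid / (len(resid) * dt)
        bA = np.clip(B0[0, 0], 1e-3, 1.5 / dt)
        bV = np.clip(B0[1, 1], 1e-3, 1.5 / dt)
        rhoB = np.clip(B0[0, 1] / np.sqrt(bA * bV), -0.95, 0.95)
        dA = np.sqrt(max(D0[0, 0], 1e-8))
        dV = np.sqrt(max(D0[1, 1], 1e-8))
        rhoD = np.clip(D0[0, 1] / (dA * dV), -0.95, 0.95)
        return np.array(
            [
                u0[0], u0[1],
                np.log(bA), np.log(bV), np.arctanh(rhoB),
                np.log(dA), np.log(dV), np.arctanh(rhoD),
                np.log(0.05), np.log(0.05),
            ]
        )

    def _log_posterior(self, x):
        try:
            params = _unpack(x)
            ll = log_likelihood(self.traj, params, kernel=self.kernel)
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf
        return ll + _log_prior(x, self.priors)

    def fit(self, method="laplace", draws=1000, seed=0, **kwargs):
        """Fit and return an :class:`OUResults`.

        ``method="laplace"`` (default) is MAP + Gaussian approximation;
        ``method="emcee"`` runs an affine-invariant ensemble sampler on the
        same posterior (slower, used mainly as a cross-check).
        """
        x0 = self._init_point()
        if method == "laplace":
            neg = lambda x: -self._log_posterior(x)
            fit = fit_map_laplace(neg, x0, n_draws=draws, seed=seed, **kwargs)
            X = fit.draws
            diag = dict(fit.diagnostics, method="laplace")
        elif method == "emcee":
            import emcee

            nwalkers = kwargs.pop("nwalkers", 32)
            nsteps = kwargs.pop("nsteps", 1500)
            burn = kwargs.pop("burn", nsteps // 2)
            rng = np.random.default_rng(seed)
            p0 = x0 + 1e-3 * rng.standard_normal((nwalkers, x0.size))
            sampler = emcee.EnsembleSampler(nwalkers, x0.size, self._log_posterior)
            sampler.random_state = np.random.RandomState(seed).get_state()
            sampler.run_mcmc(p0, nsteps, progress=False)
            chain = sampler.get_chain(discard=burn, flat=True)
            idx = rng.choice(len(chain), size=min(draws, len(chain)), replace=False)
            X = chain[idx]
            diag = {
                "method": "emcee",
                "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
            }
        else:
            raise ValueError(f"unknown method {method!r}")
        if X.shape[0] < 1:
            raise RuntimeError("no posterior draws produced")
        return OUResults(model=self, draws=_draws_frame(X), diagnostics=diag, seed=seed)


@dataclass
class OUResults:
    """Posterior over OU parameters for one subject."""

    model: OUModel
    draws: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def descriptor(self) -> np.ndarray:
        """Posterior-mean descriptor [U_A, U_V, B_AA, B_AV, B_VV, D_AA, D_AV, D_VV]."""
        return self.draws[list(DESCRIPTOR_LABELS)].mean().to_numpy()

    def params_at(self, i) -> OUParams:
        """OUParams reconstructed from posterior draw ``i``."""
        row = self.draws.iloc[i]
        B = np.array([[row.B_AA, row.B_AV], [row.B_AV, row.B_VV]])
        D = np.array([[row.D_AA, row.D_AV], [row.D_AV, row.D_VV]])
        R = np.diag([row.R_A, row.R_V])
        return OUParams(np.array([row.U_A, row.U_V]), B, D, R, validate=False)

    def mean_params(self) -> OUParams:
        """OUParams assembled from element-wise posterior means."""
        m = self.draws.mean()
        B = np.array([[m.B_AA, m.B_AV], [m.B_AV, m.B_VV]])
        D = np.array([[m.D_AA, m.D_AV], [m.D_AV, m.D_VV]])
        return OUParams(
            np.array([m.U_A, m.U_V]), B, D, np.diag([m.R_A, m.R_V]), validate=False
        )

    def simulate(self, n_steps=None, dt=None, seed=0, draw=None, s0=None) -> Trajectory:
        """Simulate a replicated trajectory from a posterior draw.

        ``draw=None`` uses the posterior-mean parameters; otherwise the
        indexed draw.  Length and step default to the fitted trajectory's.
        """
        params = self.mean_params() if draw is None else self.params_at(draw)
        n_steps = self.model.traj.n if n_steps is None else n_steps
        dt = self.model.traj.dt if dt is None else dt
        return simulate(params, n_steps, dt, s0=s0, seed=seed)

    def summary(self, mass=0.95) -> pd.DataFrame:
        rows = []
        for col in self.draws.columns:
            lo, hi = hdi(self.draws[col].to_numpy(), mass)
            rows.append(
                {
                    "param": col,
                    "mean": self.draws[col].mean(),
                    "sd": self.draws[col].std(ddof=1),
                    "hdi_lo": lo,
                    "hdi_hi": hi,
                }
            )
        return pd.DataFrame(rows).set_index("param")
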