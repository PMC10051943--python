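"""Bayesian (truncated-)normal regression of Likert ratings on causes.

The causal outcome model regresses a subject's 7-point social-trait rating
on the standardized affect-dynamics descriptor p and the substitute
confounder c_hat::

    z ~ TruncNormal(intercept + p' eta + c_hat' gamma, sigma^2; 1, 7)

Two baselines share the machinery: a vanilla Bayesian linear regression
(no truncation, no confounder) and a purely associative truncated
regression (truncation, no confounder).  Coefficients are read as unit-
increase causal effects on the standardized-cause scale; the population-
averaged outcome under the fitted model is obtained by the G-formula
(Monte-Carlo average of the truncated-normal mean over subjects and
posterior draws).  Significance is judged by whether zero falls outside
the 95% highest-density interval of a coefficient's posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bayes import (
    fit_map_laplace,
    hdi,
    truncnorm_logpdf,
    truncnorm_mean,
)
from .factor import CauseMatrix, _values

__all__ = [
    "RatingOutcomeModel",
    "OutcomeResults",
    "hdi",
    "significance_table",
]

_LOG2PI = np.log(2 * np.pi)


class RatingOutcomeModel:
    """One trait's rating model; see the module docstring.

    Parameters
    ----------
    z : array of float
        One consensus rating per subject, inside the truncation bounds.
    P : CauseMatrix or (S, L) ndarray
        Standardized causes.
    confounders : (S, K) ndarray, optional
        Substitute confounders; omit for the non-causal baselines.
    truncated : bool
        Truncated-normal likelihood if True, plain normal otherwise.
    bounds : (lo, hi)
        Truncation bounds of the rating scale.
    """

    def __init__(self, z, P, confounders=None, truncated=True, bounds=(1.0, 7.0),
                 priors=None):
        self.z = np.asarray(z, float).ravel()
        self.P = _values(P)
        if self.P.shape[0] != self.z.size:
            raise ValueError("z and P row counts differ")
        self.bounds = (float(bounds[0]), float(bounds[1]))
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy lo < hi")
        if ((self.z < self.bounds[0]) | (self.z > self.bounds[1])).any():
            raise ValueError("ratings outside the truncation bounds")
        self.confounders = (
            None if confounders is None else np.asarray(confounders, float)
        )
        if self.confounders is not None and self.confounders.shape[0] != self.z.size:
            raise ValueError("confounder row count mismatch")
        self.truncated = bool(truncated)
        # coefficient priors N(0,1); intercept N(mid, 2^2); sigma ~ HalfNormal(1)
        mid = 0.5 * (self.bounds[0] + self.bounds[1])
        self.priors = dict(
            {"coef_sd": 1.0, "intercept_loc": mid, "intercept_sd": 2.0, "sigma_scale": 1.0},
            **(priors or {}),
        )

    @property
    def n_coef(self) -> int:
        k = 0 if self.confounders is None else self.confounders.shape[1]
        return 1 + self.P.shape[1] + k  # intercept + eta + gamma

    def _design(self, P=None, confounders=None):
        P = self.P if P is None else _values(P)
        confounders = self.confounders if confounders is None else confounders
        cols = [np.ones(P.shape[0]), *P.T]
        if self.confounders is not None:
            cols.extend(np.asarray(confounders, float).T)
        return np.column_stack(cols)

    def _neg_logpost(self, x):
        X = self._design()
        beta, log_sigma = x[:-1], x[-1]
        sigma = np.exp(log_sigma)
        mu = X @ beta
        if self.truncated:
            ll = truncnorm_logpdf(self.z, mu, sigma, *self.bounds).sum()
        else:
            ll = (-0.5 * ((self.z - mu) / sigma) ** 2 - log_sigma - 0.5 * _LOG2PI).sum()
        pr = self.priors
        lp = -0.5 * ((beta[0] - pr["intercept_loc"]) / pr["intercept_sd"]) ** 2
        lp += -0.5 * float(beta[1:] @ beta[1:]) / pr["coef_sd"] ** 2
        lp += -0.5 * sigma**2 / pr["sigma_scale"] ** 2 + log_sigma
        return -(ll + lp)

    def fit(self, draws=1000, seed=0):
        X = self._design()
        # ridge-regularized least squares start, sigma from residuals
        XtX = X.T @ X + 1e-6 * np.eye(X.shape[1])
        beta0 = np.linalg.solve(XtX, X.T @ self.z)
        resid = self.z - X @ beta0
        s0 = max(resid.std(), 1e-2)
        x0 = np.concatenate([beta0, [np.log(s0)]])
        # keep sigma off the degenerate sigma -> 0 boundary
        bnds = [(None, None)] * len(beta0) + [(np.log(1e-2), np.log(1e2))]
        fit = fit_map_laplace(
            self._neg_logpost, x0, n_draws=draws, seed=seed, bounds=bnds
        )
        names = ["intercept"]
        names += [f"eta_{i}" for i in range(self.P.shape[1])]
        if self.confounders is not None:
            names += [f"gamma_{j}" for j in range(self.confounders.shape[1])]
        df = pd.DataFrame(fit.draws[:, :-1], columns=names)
        df["sigma"] = np.exp(fit.draws[:, -1])
        return OutcomeResults(model=self, draws=df, diagnostics=dict(fit.diagnostics))


@dataclass
class OutcomeResults:
    """Posterior over (intercept, eta, gamma, sigma) for one trait."""

    model: RatingOutcomeModel
    draws: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def coef_names(self):
        return [c for c in self.draws.columns if c != "sigma"]

    def summary(self, mass=0.95) -> pd.DataFrame:
        rows = []
        for col in self.draws.columns:
            x = self.draws[col].to_numpy()
            lo, hi = hdi(x, mass)
            rows.append(
                {
                    "param": col,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "hdi_lo": lo,
                    "hdi_hi": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def _mu_draws(self, P=None, confounders=None):
        X = self.model._design(P, confounders)
        B = self.draws[self.coef_names].to_numpy()
        return X @ B.T  # (S, M)

    def ate(self, P=None, confounders=None, shift=None, mass=0.95) -> dict:
        """Per-coefficient causal effects and the G-formula population average.

        ``shift`` may map a cause column index to an additive intervention;
        the population average is then computed under the shifted causes.
        Returns a dict with the coefficient table and the averaged outcome
        (mean over subjects and posterior draws of the truncated-normal
        mean, or the linear predictor for a non-truncated model).
        """
        P_use = self.model.P if P is None else _values(P)
        if shift:
            P_use = P_use.copy()
            for j, delta in shift.items():
                P_use[:, j] += delta
        mu = self._mu_draws(P_use, confounders)
        sigma = self.draws["sigma"].to_numpy()[None, :]
        if self.model.truncated:
            vals = truncnorm_mean(mu, sigma, *self.model.bounds)
        else:
            vals = mu
        per_draw = vals.mean(axis=0)  # average over subjects, per draw
        lo, hi = hdi(per_draw, mass)
        return {
            "effects": self.summary(mass).loc[self.coef_names],
            "average_outcome": float(per_draw.mean()),
            "average_outcome_hdi": (lo, hi),
        }

    def pll(self, z, P, confounders=None, likelihood="density") -> float:
        """Average predictive log likelihood on held-out subjects.

        Per subject, the log likelihood of the observed rating is averaged
        over posterior draws (expectation of the log, not log of the
        expectation), then averaged over subjects.  ``likelihood`` selects
        the continuous truncated-normal density at the rating value
        (default, matching the fitted likelihood) or the probability mass
        of the rating's rounding interval (``"interval"``).
        """
        z = np.asarray(z, float).ravel()
        if z.size == 0:
            raise ValueError("empty test set")
        mu = self._mu_draws(P, confounders)  # (S, M)
        sigma = self.draws["sigma"].to_numpy()[None, :]
        lo, hi = self.model.bounds
        if not self.model.truncated:
            ll = -0.5 * ((z[:, None] - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
        elif likelihood == "density":
            ll = truncnorm_logpdf(z[:, None], mu, sigma, lo, hi)
        elif likelihood == "interval":
            from scipy import stats

            a = (np.maximum(z[:, None] - 0.5, lo) - mu) / sigma
            b = (np.minimum(z[:, None] + 0.5, hi) - mu) / sigma
            alo = (lo - mu) / sigma
            bhi = (hi - mu) / sigma
            zmass = stats.norm.cdf(bhi) - stats.norm.cdf(alo)
            mass = (stats.norm.cdf(b) - stats.norm.cdf(a)) / zmass
            ll = np.log(np.clip(mass, 1e-300, None))
        else:
            raise ValueError(f"unknown likelihood {likelihood!r}")
        return float(ll.mean(axis=1).mean())


def significance_table(results_by_trait, mass=0.95, only_significant=True) -> pd.DataFrame:
    """Coefficient table across traits, optionally filtered to 0-excluding HDIs.

    ``results_by_trait`` maps a trait name to an :class:`OutcomeResults`.
    """
    rows = []
    for trait, res in results_by_trait.items():
        summ = res.summary(mass)
        for name, row in summ.iterrows():
            if name in ("sigma", "intercept"):  # not effects; trivially nonzero
                continue
            rows.append({"trait": trait, "coefficient": name, **row.to_dict()})
    df = pd.DataFrame(rows)
    if only_significant and len(df):
        df = df[df["significant"]].reset_index(drop=True)
    return df
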