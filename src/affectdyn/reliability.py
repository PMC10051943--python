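"""Rater simulation, inter-rater reliability and predictive evaluation.

A fitted outcome model can impersonate raters: each simulated rater is one
joint draw (eta_r, gamma_r, sigma_r) from the coefficient posterior, and
its rating of a subject is the nearest integer of a truncated-normal draw
around that rater's linear predictor.  Agreement within and across the
human and simulated rater pools is quantified with the intraclass
correlation coefficient (two-way random effects; single-measure absolute
agreement by default), and predictive quality of competing outcome models
on held-out subjects with the average predictive log likelihood (PLL),
including a covariate-shift stress test on an "uncommon" subject split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._bayes import truncnorm_rvs
from .factor import PPCAModel
from .outcome import RatingOutcomeModel

__all__ = [
    "sample_raters",
    "ICCResult",
    "icc",
    "icc_band",
    "reliability_study",
    "consensus_ratings",
    "shift_benchmark",
]


def sample_raters(results_by_trait, P, confounders, n_raters=6, seed=0,
                  subject_ids=None) -> pd.DataFrame:
    """Simulate ``n_raters`` raters from the outcome-model posteriors.

    For each rater and trait one joint posterior draw is taken; ratings are
    ``round(TruncNormal(mu, sigma^2; lo, hi))`` per subject.  Returns a long
    DataFrame (subject_id, rater_id, trait, rating) with rater ids "sim0"...
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for trait, res in results_by_trait.items():
        X = res.model._design(P, confounders)
        lo, hi = res.model.bounds
        for r in range(n_raters):
            i = int(rng.integers(res.n_draws)) if hasattr(res, "n_draws") else int(
                rng.integers(len(res.draws))
            )
            draw = res.draws.iloc[i]
            beta = draw[res.coef_names].to_numpy(float)
            sigma = float(draw["sigma"])
            mu = X @ beta
            z = np.rint(truncnorm_rvs(rng, mu, sigma, lo, hi)).astype(int)
            z = np.clip(z, int(np.ceil(lo)), int(np.floor(hi)))
            ids = subject_ids if subject_ids is not None else range(len(z))
            rows.extend(
                {"subject_id": s, "rater_id": f"sim{r}", "trait": trait, "rating": int(v)}
                for s, v in zip(ids, z)
            )
    return pd.DataFrame(rows)


@dataclass
class ICCResult:
    value: float
    variant: str
    band: str
    n_subjects: int
    n_raters: int


def icc_band(value: float) -> str:
    """Qualitative agreement band for an ICC value."""
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def icc(ratings, variant="single") -> ICCResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    ``ratings`` is a complete subjects x raters matrix.  ``variant`` is
    ``"single"`` (agreement of a single rater, ICC(2,1)) or ``"average"``
    (agreement of the k-rater average, ICC(2,k)).  Computed from the
    two-way ANOVA mean squares; identical raters over varying subjects give
    exactly 1, and zero between-subject variance is reported as 0 with a
    warning.
    """
    X = np.asarray(ratings, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be a (subjects >= 2) x (raters >= 2) matrix")
    if not np.isfinite(X).all():
        raise ValueError("ratings matrix has missing cells")
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ((X - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        warnings.warn("zero between-subject variance; ICC undefined, returning 0")
        value = 0.0
    elif variant == "single":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif variant == "average":
        value = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ICCResult(float(value), variant, icc_band(float(value)), n, k)


def _pivot(df, trait):
    sub = df[df["trait"] == trait]
    wide = sub.pivot(index="subject_id", columns="rater_id", values="rating")
    if wide.isna().any().any():
        raise ValueError(f"incomplete ratings for trait {trait!r}")
    return wide.to_numpy(float)


def reliability_study(human_df, simulated_df, traits=None, variant="single") -> pd.DataFrame:
    """Per-trait ICC of human raters, simulated raters and the pooled set.

    Both inputs are long DataFrames (subject_id, rater_id, trait, rating);
    rater ids must not collide across pools.  An ``average`` row holds the
    column means.
    """
    if traits is None:
        traits = sorted(set(human_df["trait"]) & set(simulated_df["trait"]))
    pooled = pd.concat([human_df, simulated_df], ignore_index=True)
    rows = []
    for trait in traits:
        rows.append(
            {
                "trait": trait,
                "icc_humans": icc(_pivot(human_df, trait), variant).value,
                "icc_model": icc(_pivot(simulated_df, trait), variant).value,
                "icc_pooled": icc(_pivot(pooled, trait), variant).value,
            }
        )
    out = pd.DataFrame(rows).set_index("trait")
    out.loc["average"] = out.mean()
    return out


def consensus_ratings(ratings_df, method="median") -> pd.DataFrame:
    """One rating per subject and trait, aggregated across raters.

    ``method="median"`` takes the across-rater median, rounding half-integer
    ties toward the scale midpoint (4); ``"mean"`` takes the rounded mean.
    Returns a subjects x traits DataFrame.
    """
    wide = ratings_df.pivot_table(
        index="subject_id", columns="trait", values="rating",
        aggfunc="median" if method == "median" else "mean",
    )
    vals = wide.to_numpy(float)
    frac = vals % 1 != 0
    toward_mid = np.where(vals > 4, np.floor(vals), np.ceil(vals))
    vals = np.where(frac, toward_mid, np.rint(vals))
    return pd.DataFrame(vals.astype(int), index=wide.index, columns=wide.columns)


def shift_benchmark(
    P,
    ratings,
    splits,
    k=2,
    seed=0,
    draws=500,
    traits=None,
) -> pd.DataFrame:
    """PLL of vanilla, truncated-associative and causal models across splits.

    Parameters
    ----------
    P : CauseMatrix
        Standardized causes for the whole cohort.
    ratings : DataFrame
        Consensus ratings, subjects x traits (rows aligned with ``P``).
    splits : dict
        Name -> (train_idx, test_idx) pairs, e.g. a random ("typical") and
        a confounder-shifted ("uncommon") split.
    Returns a DataFrame indexed by split with one PLL column per model,
    averaged over traits.
    """
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = list(ratings.columns)
    rows = []
    for name, (train_idx, test_idx) in splits.items():
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        P_train, P_test = P.values[train_idx], P.values[test_idx]
        factor = PPCAModel(P_train, k=k, standardize=False).fit(
            n_draws=200, seed=int(rng.integers(2**31))
        )
        c_train = factor.confounders()
        c_test = factor.confounders(P_test)
        pll = {"vanilla": [], "truncated": [], "causal": []}
        for trait in traits:
            z = ratings[trait].to_numpy(float)
            z_tr, z_te = z[train_idx], z[test_idx]
            specs = {
                "vanilla": dict(confounders=None, truncated=False),
                "truncated": dict(confounders=None, truncated=True),
                "causal": dict(confounders=c_train, truncated=True),
            }
            for mname, kw in specs.items():
                res = RatingOutcomeModel(z_tr, P_train, **kw).fit(
                    draws=draws, seed=int(rng.integers(2**31))
                )
                conf = c_test if mname == "causal" else None
                pll[mname].append(res.pll(z_te, P_test, conf))
        rows.append(
            {"split": name, **{f"pll_{m}": float(np.mean(v)) for m, v in pll.items()}}
        )
    return pd.DataFrame(rows).set_index("split")
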