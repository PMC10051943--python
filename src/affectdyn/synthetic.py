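"""Synthetic cohorts with known ground truth.

Emulates the structure of a continuously annotated dyadic-interaction
corpus: ~23 subjects, 6 raters, ~5-minute valence/arousal trajectories at
40 ms steps, and 7-point ratings of five social-participation traits
(agreement, dominance, engagement, performance, rapport).  A K-dimensional
latent confounder per subject influences both the subject's OU
affect-dynamics parameters (the causes) and the ratings (the outcomes), so
every downstream stage — fusion, OU inference, factor modelling, causal
estimation, rater simulation — can be validated by recovery against known
truth.

Population heterogeneity is generated in an unconstrained natural
parameter space ``[U_A, U_V, log B_AA, log B_VV, atanh rho_B, log d_A,
log d_V, atanh rho_D]`` (positive entries through an exponential link,
correlations through tanh): theta_s = baseline + loadings' c_s + noise.
Rating means use the within-cohort standardized descriptor, so the
generator's causal coefficients live on the same scale the outcome model
estimates, with intercept fixed at the scale midpoint (4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bayes import truncnorm_rvs
from .ou import OUParams, simulate

__all__ = ["TRAITS", "CohortSpec", "GroundTruth", "generate_cohort",
           "make_shifted_test_split"]

TRAITS = ("agreement", "dominance", "engagement", "performance", "rapport")

#: baseline natural parameters: home base near the origin, moderate pull
#: (B diag ~ 1.2-1.5 1/s), stationary spread ~0.3 annotation units
_DEFAULT_BASELINE = np.array(
    [0.0, 0.0, np.log(1.5), np.log(1.2), np.arctanh(0.2),
     np.log(0.5), np.log(0.45), np.arctanh(0.1)]
)

#: confounder -> natural-parameter loadings (K=2 by 8)
_DEFAULT_LOADINGS = np.array(
    [
        [0.50, 0.30, 0.40, 0.00, 0.30, 0.40, 0.00, 0.20],
        [0.00, 0.40, 0.00, 0.40, -0.20, 0.00, 0.40, 0.30],
    ]
)

#: causal coefficients of the standardized descriptor on each trait's mean;
#: qualitative pattern: agreement <- valence home base, dominance and
#: engagement <- arousal home base, engagement also <- arousal diffusion
_DEFAULT_ETA = np.zeros((5, 8))
_DEFAULT_ETA[0, 1] = 0.5   # agreement ~ U_V
_DEFAULT_ETA[1, 0] = 0.55  # dominance ~ U_A
_DEFAULT_ETA[2, 0] = 0.6   # engagement ~ U_A
_DEFAULT_ETA[2, 5] = 0.45  # engagement ~ D_AA

#: direct confounder -> rating effects (5 traits by K=2)
_DEFAULT_GAMMA = np.array(
    [[0.8, 0.0], [0.0, 0.8], [0.5, 0.5], [0.3, -0.3], [0.0, 0.0]]
)


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 23
    n_raters: int = 6
    n_traits: int = 5
    duration_s: float = 300.0
    dt: float = 0.04
    k_confounder: int = 2
    baseline_natural: np.ndarray = field(
        default_factory=lambda: _DEFAULT_BASELINE.copy()
    )
    confounder_loading_causes: np.ndarray = field(
        default_factory=lambda: _DEFAULT_LOADINGS.copy()
    )
    true_eta: np.ndarray = field(default_factory=lambda: _DEFAULT_ETA.copy())
    true_gamma: np.ndarray = field(default_factory=lambda: _DEFAULT_GAMMA.copy())
    cause_noise_sd: float = 0.3       # idiosyncratic spread of natural params
    sigma_rating: float = 0.5
    rater_trajectory_noise_sd: float = 0.05
    obs_noise_sd: float = 0.01        # observation noise R^(1/2) of the shared path
    rating_intercept: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.baseline_natural = np.asarray(self.baseline_natural, float).reshape(8)
        self.confounder_loading_causes = np.asarray(
            self.confounder_loading_causes, float
        ).reshape(self.k_confounder, 8)
        self.true_eta = np.asarray(self.true_eta, float).reshape(self.n_traits, 8)
        self.true_gamma = np.asarray(self.true_gamma, float).reshape(
            self.n_traits, self.k_confounder
        )
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_rating <= 0:
            raise ValueError("sigma_rating must be positive")
        steps = self.duration_s / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("duration_s must be a whole number of dt steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.dt))

    @property
    def subject_ids(self):
        return [f"S{i:03d}" for i in range(self.n_subjects)]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: CohortSpec
    confounders: np.ndarray       # (S, K)
    params: list                  # OUParams per subject
    descriptors: np.ndarray       # (S, 8) raw descriptor p_s
    descriptors_std: np.ndarray   # (S, 8) within-cohort standardized
    rating_means: np.ndarray      # (S, n_traits) latent rating means

    def to_json(self, path):
        subjects = {}
        for i, sid in enumerate(self.spec.subject_ids):
            p = self.params[i]
            subjects[sid] = {
                "c": self.confounders[i].tolist(),
                "U": p.U.tolist(),
                "B": p.B.tolist(),
                "D": p.D.tolist(),
                "R": p.R.tolist(),
                "p": self.descriptors[i].tolist(),
            }
        with open(path, "w") as fh:
            json.dump({"subjects": subjects}, fh, indent=1)


def _natural_to_params(theta, obs_noise_sd):
    return OUParams.from_natural(
        theta[:2],
        (np.exp(theta[2]), np.exp(theta[3])),
        np.tanh(theta[4]),
        (np.exp(theta[5]), np.exp(theta[6])),
        np.tanh(theta[7]),
        (obs_noise_sd, obs_noise_sd),
    )


def _draw_subject_params(spec, rng, max_retries=100):
    """Confounders and OU parameters, redrawing Euler-unstable subjects."""
    S = spec.n_subjects
    c = rng.standard_normal((S, spec.k_confounder))
    params = []
    b_max = 1.9 / spec.dt  # keep (I - B dt) stable with margin
    for i in range(S):
        for attempt in range(max_retries + 1):
            theta = (
                spec.baseline_natural
                + spec.confounder_loading_causes.T @ c[i]
                + spec.cause_noise_sd * rng.standard_normal(8)
            )
            if max(np.exp(theta[2]), np.exp(theta[3])) < b_max:
                break
            if attempt == max_retries:
                raise RuntimeError(
                    "could not draw stable OU parameters; loadings or noise too large"
                )
            c[i] = rng.standard_normal(spec.k_confounder)
        params.append(_natural_to_params(theta, spec.obs_noise_sd))
    return c, params


def generate_cohort(spec, with_trajectories=True):
    """Sample one cohort: ground truth, trajectories and ratings.

    Returns ``(GroundTruth, trajectories_df, ratings_df)``;
    ``trajectories_df`` is None when ``with_trajectories=False`` (useful for
    causal-stage studies that work from the true descriptors directly).
    All randomness derives from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_pop, rng_traj, rng_rate = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    c, params = _draw_subject_params(spec, rng_pop)
    p = np.stack([par.descriptor for par in params])
    p_std = (p - p.mean(axis=0)) / p.std(axis=0, ddof=0)
    mu = spec.rating_intercept + p_std @ spec.true_eta.T + c @ spec.true_gamma.T

    traits = list(TRAITS[: spec.n_traits])
    rating_rows = []
    for i, sid in enumerate(spec.subject_ids):
        for r in range(spec.n_raters):
            draws = truncnorm_rvs(rng_rate, mu[i], spec.sigma_rating, 1.0, 7.0)
            for j, trait in enumerate(traits):
                rating_rows.append(
                    {
                        "subject_id": sid,
                        "rater_id": f"r{r}",
                        "trait": trait,
                        "rating": int(np.clip(np.rint(draws[j]), 1, 7)),
                    }
                )
    ratings_df = pd.DataFrame(rating_rows)

    traj_df = None
    if with_trajectories:
        frames = []
        t = np.arange(spec.n_steps) * spec.dt
        for i, sid in enumerate(spec.subject_ids):
            shared = simulate(
                params[i], spec.n_steps, spec.dt,
                seed=np.random.default_rng(rng_traj.integers(2**31)),
            )
            for r in range(spec.n_raters):
                noisy = shared.y + spec.rater_trajectory_noise_sd * rng_traj.standard_normal(
                    shared.y.shape
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "rater_id": f"r{r}",
                            "t": t,
                            "valence": noisy[:, 1],
                            "arousal": noisy[:, 0],
                        }
                    )
                )
        traj_df = pd.concat(frames, ignore_index=True)

    gt = GroundTruth(
        spec=spec,
        confounders=c,
        params=params,
        descriptors=p,
        descriptors_std=p_std,
        rating_means=mu,
    )
    return gt, traj_df, ratings_df


def make_shifted_test_split(confounders, shift, fraction, seed=0, bandwidth=1.0):
    """Train/test split with the test set drawn from a shifted confounder region.

    Test subjects are sampled without replacement with probability
    proportional to the Gaussian likelihood ratio between a population
    displaced by ``shift`` and the base N(0, I) population (an exponential
    tilt ``exp(c . shift / bandwidth^2)``), so ``shift = 0`` reduces
    exactly to a uniform random split.  Returns ``(train_idx, test_idx)``,
    disjoint and exhaustive, with ``len(test_idx) = round(fraction * S)``.
    """
    c = np.asarray(confounders, float)
    if c.ndim != 2:
        raise ValueError("confounders must be (S, K)")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    S = c.shape[0]
    n_test = int(round(fraction * S))
    if n_test == 0:
        raise ValueError("fraction yields an empty test set")
    shift = np.broadcast_to(np.asarray(shift, float), (c.shape[1],))
    rng = np.random.default_rng(seed)
    logw = (c @ shift) / bandwidth**2
    w = np.exp(logw - logw.max())
    w /= w.sum()
    test_idx = np.sort(rng.choice(S, size=n_test, replace=False, p=w))
    train_idx = np.setdiff1d(np.arange(S), test_idx)
    return train_idx, test_idx
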