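"""Evaluator Weighted Estimator (EWE) fusion of multi-rater annotations.

Several raters annotate the same subject's valence/arousal trajectory on a
common time grid; the consensus trajectory is their weighted average, where
each rater's weight is its mean Pearson correlation with every other rater
(a rater that agrees with the group counts more).  Each pairwise
correlation is clipped below at zero before averaging — an anticorrelated
pair contributes no agreement rather than negative agreement, so one
contrarian rater cannot drag down the weights of raters who agree with
each other.  Weights are computed independently for the arousal and
valence dimensions and normalised to sum to one.
"""

from __future__ import annotations

import warnings

import numpy as np

from .ou import Trajectory

__all__ = ["ewe_fuse", "ewe_weights"]


def _stack(trajectories):
    trajs = list(trajectories)
    if len(trajs) < 2:
        raise ValueError("EWE fusion needs at least 2 raters")
    t0 = trajs[0].t
    for tr in trajs[1:]:
        if tr.n != trajs[0].n or not np.allclose(tr.t, t0):
            raise ValueError("raters must share an identical time grid")
    return t0, np.stack([tr.y for tr in trajs])  # (R, N, 2)


def ewe_weights(Y, include_self=False):
    """Per-dimension EWE weights for a stacked (R, N, 2) annotation array.

    Returns a (2, R) array (rows: arousal, valence).  A rater with a
    constant trajectory has undefined correlations and receives weight 0;
    if every weight clips to zero the weights fall back to uniform.
    """
    R = Y.shape[0]
    W = np.empty((2, R))
    for dim in range(2):
        X = Y[:, :, dim]
        sd = X.std(axis=1)
        const = sd == 0
        if (~const).sum() < 2:
            raise ValueError(
                "fewer than two raters with nonzero variance in a dimension"
            )
        with np.errstate(invalid="ignore"):
            C = np.clip(np.corrcoef(X), 0.0, None)
        w = np.zeros(R)
        for r in range(R):
            if const[r]:
                warnings.warn(f"rater {r} constant in dimension {dim}; weight set to 0")
                continue
            others = [q for q in range(R) if (include_self or q != r) and not const[q]]
            w[r] = np.nanmean(C[r, others])
        if w.sum() == 0:
            warnings.warn("all EWE weights clipped to 0; falling back to uniform")
            w = np.ones(R)
        W[dim] = w / w.sum()
    return W


def ewe_fuse(trajectories, include_self=False, return_weights=False):
    """Fuse a list of per-rater :class:`~affectdyn.ou.Trajectory` into one.

    The fused value at every time point is a convex combination of the
    raters' values, so it lies within their pointwise min/max, and the
    result is invariant to the order in which raters are listed.
    """
    t, Y = _stack(trajectories)
    W = ewe_weights(Y, include_self=include_self)
    fused = np.stack(
        [np.tensordot(W[dim], Y[:, :, dim], axes=1) for dim in range(2)], axis=1
    )
    out = Trajectory(t=t, y=fused)
    if return_weights:
        return out, W
    return out
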