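"""Truncated Bayesian outcome model, HDI, ATE and significance filtering."""

import numpy as np
import pandas as pd
import pytest

from affectdyn import (
    CauseMatrix,
    PPCAModel,
    RatingOutcomeModel,
    hdi,
    significance_table,
)
from affectdyn._bayes import truncnorm_rvs
from affectdyn.outcome import OutcomeResults


def _point_mass_results(P, eta, intercept=4.0, sigma=0.01, gamma=None, chat=None,
                        n=200, truncated=True):
    """OutcomeResults with a degenerate (single-value) posterior, for
    checking downstream algebra against closed forms."""
    z = np.full(P.shape[0], 4.0)
    model = RatingOutcomeModel(z, P, confounders=chat, truncated=truncated)
    cols = {"intercept": intercept}
    cols.update({f"eta_{i}": eta[i] for i in range(P.shape[1])})
    if gamma is not None:
        cols.update({f"gamma_{j}": gamma[j] for j in range(len(gamma))})
    cols["sigma"] = sigma
    draws = pd.DataFrame({k: np.full(n, v) for k, v in cols.items()})
    return OutcomeResults(model=model, draws=draws)


class TestHdi:
    def test_point_mass_zero_width(self):
        lo, hi = hdi(np.full(100, 3.7))
        assert lo == hi == 3.7

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_width(self):
        x = np.random.default_rng(1).random(200_000)
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_permutation_invariance(self, rng):
        x = rng.gamma(2.0, size=5000)
        assert hdi(x) == hdi(rng.permutation(x))

    def test_agrees_with_arviz_on_skewed_sample(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.gamma(2.0, size=50_000)
        ours = hdi(x, 0.95)
        theirs = az.hdi(x, hdi_prob=0.95)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)


class TestFit:
    def test_noiseless_recovery(self, rng):
        """Rounded noiseless ratings with interior means pin eta tightly."""
        S = 500
        P = CauseMatrix.from_raw(rng.standard_normal((S, 8)))
        eta = np.array([0.3, -0.25, 0.2, 0.0, 0.15, 0.0, -0.2, 0.1])
        mu = 4.0 + P.values @ eta
        assert mu.min() > 1.5 and mu.max() < 6.5
        z = np.clip(np.rint(mu), 1, 7)
        res = RatingOutcomeModel(z, P).fit(draws=500, seed=0)
        est = res.summary().loc[[f"eta_{i}" for i in range(8)], "mean"].to_numpy()
        assert np.abs(est - eta).max() < 0.05

    def test_no_confounding_causal_matches_associative(self, rng):
        """With gamma = 0 and causes independent of any factor, adding the
        substitute confounder leaves the eta estimates within posterior sd."""
        S = 300
        P = CauseMatrix.from_raw(rng.standard_normal((S, 8)))
        eta = np.array([0.4, 0, 0, -0.3, 0, 0, 0.2, 0])
        z = np.clip(np.rint(4 + P.values @ eta + 0.3 * rng.standard_normal(S)), 1, 7)
        chat = PPCAModel(P, k=2).fit(n_draws=100, seed=0).confounders()
        causal = RatingOutcomeModel(z, P, confounders=chat).fit(draws=500, seed=1)
        assoc = RatingOutcomeModel(z, P).fit(draws=500, seed=2)
        names = [f"eta_{i}" for i in range(8)]
        diff = (causal.summary().loc[names, "mean"] - assoc.summary().loc[names, "mean"]).abs()
        sd = causal.summary().loc[names, "sd"]
        assert (diff < sd).all()

    def test_ratings_outside_scale_rejected(self, rng):
        P = rng.standard_normal((10, 8))
        with pytest.raises(ValueError, match="outside"):
            RatingOutcomeModel(np.array([3, 4, 8, 2, 1, 5, 6, 7, 4, 3]), P)


class TestAte:
    def test_null_effects_average_is_intercept(self, rng):
        P = rng.standard_normal((100, 8))
        res = _point_mass_results(P, eta=np.zeros(8), intercept=4.0, sigma=0.01)
        out = res.ate()
        assert out["average_outcome"] == pytest.approx(4.0, abs=1e-6)

    def test_unit_intervention_shifts_by_eta_when_nonbinding(self, rng):
        P = 0.3 * rng.standard_normal((100, 8))
        eta = np.array([0.25, 0, 0, 0, 0, 0, 0, 0])
        res = _point_mass_results(P, eta=eta, sigma=0.01)
        base = res.ate()["average_outcome"]
        shifted = res.ate(shift={0: 1.0})["average_outcome"]
        assert shifted - base == pytest.approx(0.25, abs=1e-6)

    def test_binding_truncation_matches_monte_carlo_oracle(self, rng):
        """With means pushed into the upper bound, the G-formula average
        equals a brute-force truncated-normal sampling estimate."""
        P = rng.standard_normal((50, 8))
        eta = np.array([1.5, 0, 0, 0, 0, 0, 0, 0])
        res = _point_mass_results(P, eta=eta, intercept=6.0, sigma=1.0)
        got = res.ate()["average_outcome"]
        mu = 6.0 + P @ eta
        draws = truncnorm_rvs(rng, np.repeat(mu, 4000), 1.0, 1.0, 7.0)
        assert got == pytest.approx(draws.mean(), abs=1e-2)


class TestSignificance:
    def test_flags_follow_hdi(self, rng):
        P = rng.standard_normal((50, 2))
        res = _point_mass_results(P, eta=np.zeros(2))
        # overwrite with stochastic draws of known location/scale
        m = len(res.draws)
        res.draws["eta_0"] = 0.57 + 0.2 * rng.standard_normal(m)  # HDI ~ (0.17, 0.97)
        res.draws["eta_1"] = 0.05 + 0.08 * rng.standard_normal(m)  # HDI straddles 0
        table = significance_table({"dominance": res})
        flagged = set(table["coefficient"])
        assert "eta_0" in flagged
        assert "eta_1" not in flagged
        full = significance_table({"dominance": res}, only_significant=False)
        assert {"eta_0", "eta_1"} <= set(full["coefficient"])


class TestPll:
    def test_point_mass_equals_direct_log_density(self, rng):
        P = rng.standard_normal((30, 8))
        eta = 0.1 * rng.standard_normal(8)
        res = _point_mass_results(P, eta=eta, sigma=0.8)
        z = np.clip(np.rint(4 + P @ eta), 1, 7)
        from affectdyn._bayes import truncnorm_logpdf

        expected = truncnorm_logpdf(z, 4 + P @ eta, 0.8, 1, 7).mean()
        assert res.pll(z, P) == pytest.approx(expected, abs=1e-9)

    def test_inflated_sigma_lowers_pll(self, rng):
        P = rng.standard_normal((30, 8))
        eta = 0.1 * rng.standard_normal(8)
        z = np.clip(np.rint(4 + P @ eta), 1, 7)
        plls = [
            _point_mass_results(P, eta=eta, sigma=s).pll(z, P) for s in (0.5, 2.0, 8.0)
        ]
        assert plls[0] > plls[1] > plls[2]

    def test_subject_order_invariance(self, rng):
        P = rng.standard_normal((40, 8))
        eta = 0.1 * rng.standard_normal(8)
        res = _point_mass_results(P, eta=eta, sigma=0.7)
        z = np.clip(np.rint(4 + P @ eta + rng.standard_normal(40)), 1, 7)
        perm = rng.permutation(40)
        assert res.pll(z, P) == pytest.approx(res.pll(z[perm], P[perm]), abs=1e-12)

    def test_empty_test_set_rejected(self, rng):
        P = rng.standard_normal((10, 8))
        res = _point_mass_results(P, eta=np.zeros(8))
        with pytest.raises(ValueError, match="empty"):
            res.pll(np.array([]), np.empty((0, 8)))
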