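"""Rater simulation, intraclass correlation and predictive evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affectdyn import icc, icc_band, reliability_study, sample_raters
from affectdyn._bayes import truncnorm_rvs
from affectdyn.reliability import consensus_ratings
from tests.test_outcome import _point_mass_results


class TestSampleRaters:
    def test_point_mass_posterior_gives_identical_deterministic_raters(self, rng):
        P = 0.3 * rng.standard_normal((40, 8))
        eta = np.array([0.5, 0, 0, 0, 0, 0, 0, 0])
        res = _point_mass_results(P, eta=eta, sigma=0.011)
        df = sample_raters({"dominance": res}, P, None, n_raters=4, seed=0)
        wide = df.pivot(index="subject_id", columns="rater_id", values="rating")
        expected = np.clip(np.rint(4 + P @ eta), 1, 7)
        for col in wide.columns:
            assert np.array_equal(wide[col].to_numpy(float), expected)

    def test_mean_far_above_scale_rates_seven(self, rng):
        """With the mean far above the scale the truncated draw mass lies in
        (6.5, 7], so every rounded rating is the ceiling value 7."""
        P = np.zeros((50, 1))
        res = _point_mass_results(P, eta=np.array([0.0]), intercept=12.0, sigma=0.5)
        df = sample_raters({"t": res}, P, None, n_raters=2, seed=3)
        assert (df["rating"] == 7).all()
        # at mu = 9 the mass below 6.5 is ~1%, so sevens still dominate
        res9 = _point_mass_results(P, eta=np.array([0.0]), intercept=9.0, sigma=0.5)
        df9 = sample_raters({"t": res9}, P, None, n_raters=2, seed=3)
        assert (df9["rating"] == 7).mean() > 0.95
        assert df9["rating"].isin([6, 7]).all()

    def test_ratings_always_on_scale(self, rng):
        P = 3 * rng.standard_normal((30, 8))
        res = _point_mass_results(P, eta=rng.standard_normal(8), sigma=2.0)
        df = sample_raters({"t": res}, P, None, n_raters=5, seed=1)
        assert df["rating"].between(1, 7).all()
        assert df["rating"].dtype.kind == "i"

    def test_rounded_truncnorm_mean_matches_analytic_oracle(self, rng):
        """Empirical mean of round(TruncNormal) vs the exact integer-mass sum."""
        mu, sigma = 4.7, 1.2
        draws = np.rint(truncnorm_rvs(rng, np.full(100_000, mu), sigma, 1, 7))
        edges = np.array([1.0, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.0])
        a, b = (1 - mu) / sigma, (7 - mu) / sigma
        Z = stats.norm.cdf(b) - stats.norm.cdf(a)
        masses = np.diff(stats.norm.cdf((edges - mu) / sigma)) / Z
        exact = (np.arange(1, 8) * masses).sum()
        assert draws.mean() == pytest.approx(exact, abs=0.01)

    def test_at_least_one_rater_required(self, rng):
        res = _point_mass_results(np.zeros((5, 1)), eta=np.array([0.0]))
        with pytest.raises(ValueError, match="n_raters"):
            sample_raters({"t": res}, np.zeros((5, 1)), None, n_raters=0)


class TestIcc:
    def test_identical_raters_give_exactly_one(self, rng):
        col = rng.integers(1, 8, size=12).astype(float)
        X = np.tile(col[:, None], (1, 5))
        assert icc(X).value == 1.0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(4, 1, size=(200, 6))
        assert abs(icc(X).value) < 0.1

    def test_hand_worked_anova_decomposition(self):
        """4 subjects x 3 raters, mean squares computed longhand."""
        X = np.array(
            [[2.0, 3.0, 2.0], [4.0, 5.0, 4.0], [6.0, 6.0, 5.0], [3.0, 4.0, 4.0]]
        )
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            (X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + grand)
            ** 2
        ).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(X).value == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_two_way_random(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(4, 1.2, size=(15, 4)) + rng.normal(0, 1, size=(15, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 4),
                "rater": np.tile(np.arange(4), 15),
                "score": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        # two-way random, absolute agreement: labelled ICC2/ICC2k or ICC(A,1)/ICC(A,k)
        single = ref.loc[ref.index.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        average = ref.loc[ref.index.isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0]
        assert icc(X, "single").value == pytest.approx(single, abs=1e-6)
        assert icc(X, "average").value == pytest.approx(average, abs=1e-6)

    def test_noise_lowers_agreement(self, rng):
        base = np.tile(rng.normal(4, 1.5, size=(60, 1)), (1, 6))
        noisy = base + rng.normal(0, 1.0, size=base.shape)
        assert icc(noisy).value < icc(base + rng.normal(0, 0.1, base.shape)).value

    def test_duplicating_the_rater_set_roughly_preserves_icc(self, rng):
        X = np.tile(rng.normal(4, 1.5, size=(80, 1)), (1, 4)) + rng.normal(
            0, 0.8, size=(80, 4)
        )
        # the sample estimator is only asymptotically duplication-invariant
        assert icc(np.hstack([X, X])).value == pytest.approx(icc(X).value, abs=0.05)

    def test_zero_between_subject_variance_warns(self):
        X = np.full((6, 3), 4.0)
        with pytest.warns(UserWarning, match="between-subject"):
            assert icc(X).value == 0.0

    def test_bands(self):
        assert icc_band(0.2) == "poor"
        assert icc_band(0.5) == "fair"
        assert icc_band(0.65) == "good"
        assert icc_band(0.8) == "excellent"


class TestReliabilityStudy:
    def _frames(self, rng, n_sub=20, n_hum=3, n_sim=3):
        base = rng.normal(4, 1.2, size=n_sub)
        rows_h, rows_s = [], []
        for r in range(n_hum):
            z = np.clip(np.rint(base + rng.normal(0, 0.5, n_sub)), 1, 7)
            rows_h += [
                {"subject_id": s, "rater_id": f"h{r}", "trait": "agreement", "rating": v}
                for s, v in enumerate(z)
            ]
        for r in range(n_sim):
            z = np.clip(np.rint(base + rng.normal(0, 0.5, n_sub)), 1, 7)
            rows_s += [
                {"subject_id": s, "rater_id": f"sim{r}", "trait": "agreement", "rating": v}
                for s, v in enumerate(z)
            ]
        return pd.DataFrame(rows_h), pd.DataFrame(rows_s)

    def test_pooled_column_uses_all_raters(self, rng):
        hum, sim = self._frames(rng)
        table = reliability_study(hum, sim)
        pooled = pd.concat([hum, sim])
        wide = pooled.pivot(index="subject_id", columns="rater_id", values="rating")
        assert wide.shape[1] == 6
        assert table.loc["agreement", "icc_pooled"] == pytest.approx(
            icc(wide.to_numpy(float)).value
        )
        assert "average" in table.index

    def test_same_generative_process_gives_similar_iccs(self, rng):
        hum, sim = self._frames(rng, n_sub=80)
        table = reliability_study(hum, sim)
        assert abs(
            table.loc["agreement", "icc_humans"] - table.loc["agreement", "icc_model"]
        ) < 0.15


class TestConsensus:
    def test_median_with_midpoint_tie_rounding(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a"] * 4 + ["b"] * 4,
                "rater_id": list("rstu") * 2,
                "trait": ["agreement"] * 8,
                "rating": [5, 6, 6, 7, 2, 3, 4, 5],  # medians 6 and 3.5
            }
        )
        out = consensus_ratings(df)
        assert out.loc["a", "agreement"] == 6
        # tie at 3.5 rounds toward the scale midpoint (up to 4)
        assert out.loc["b", "agreement"] == 4

    def test_mean_variant(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "rater_id": list("rst"),
                "trait": ["dominance"] * 3,
                "rating": [4, 5, 7],
            }
        )
        assert consensus_ratings(df, method="mean").loc["a", "dominance"] == 5
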