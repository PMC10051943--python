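"""Ornstein-Uhlenbeck state-space model: simulation, likelihood, inference."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from affectdyn import DESCRIPTOR_LABELS, OUModel, OUParams, Trajectory, log_likelihood, simulate
from affectdyn.ou import OUResults, _draws_frame


def _params(u=(0.0, 0.0), b=(1.0, 1.0), rho_b=0.0, d=(0.5, 0.5), rho_d=0.0, r=(0.0, 0.0)):
    return OUParams.from_natural(u, b, rho_b, d, rho_d, r)


class TestSimulate:
    def test_fixed_point_of_drift(self):
        """With no noise and s0 at the home base, the trajectory stays put."""
        p = OUParams(U=[0.3, -0.2], B=np.eye(2), D=np.zeros((2, 2)))
        traj = simulate(p, 50, 0.04, s0=p.U, seed=0)
        assert np.allclose(traj.y, p.U)

    def test_linear_decay_toward_home_base(self):
        """Scalar dampening contracts the deviation by (1 - b dt) per step."""
        b, dt = 1.5, 0.05
        p = OUParams(U=[0.0, 0.0], B=b * np.eye(2), D=np.zeros((2, 2)))
        s0 = np.array([1.0, -2.0])
        traj = simulate(p, 20, dt, s0=s0, seed=0)
        for k in range(20):
            assert np.allclose(traj.y[k], s0 * (1 - b * dt) ** k)

    def test_stationary_variance_matches_lyapunov(self):
        """Long-run sample variance approaches D / (2b) for isotropic B."""
        p = OUParams(U=[0.0, 0.0], B=np.eye(2), D=0.5 * np.eye(2))
        traj = simulate(p, 200_000, 0.04, seed=3)
        target = p.stationary_cov()  # 0.25 * I
        assert np.allclose(np.diag(target), 0.25)
        emp = traj.y.var(axis=0)
        assert np.allclose(emp, 0.25, rtol=0.05)

    def test_euler_instability_raises(self):
        p = OUParams(U=[0, 0], B=60.0 * np.eye(2), D=0.1 * np.eye(2))
        with pytest.raises(ValueError, match="unstable"):
            simulate(p, 10, 0.04)

    def test_seeded_determinism(self, ou_true_params):
        a = simulate(ou_true_params, 200, 0.04, seed=9)
        b = simulate(ou_true_params, 200, 0.04, seed=9)
        assert np.array_equal(a.y, b.y)


class TestTrajectoryValidation:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(t=[0.0, 0.1, 0.3], y=np.zeros((3, 2)))

    def test_rejects_too_short(self):
        with pytest.raises(ValueError, match="3 samples"):
            Trajectory(t=[0.0, 0.1], y=np.zeros((2, 2)))


class TestLogLikelihood:
    @pytest.mark.parametrize("n", [3, 5, 60])
    def test_matches_naive_per_transition_oracle(self, n, rng):
        """Vectorized likelihood equals a term-by-term scipy computation."""
        p = _params(u=(0.2, -0.1), b=(1.2, 0.8), rho_b=0.25, d=(0.6, 0.4), rho_d=-0.3)
        traj = simulate(p, n, 0.04, seed=rng.integers(2**31))
        ours = log_likelihood(traj, p)
        dt = traj.dt
        oracle = 0.0
        for k in range(n - 1):
            mean = traj.y[k] + p.B @ (p.U - traj.y[k]) * dt
            oracle += multivariate_normal.logpdf(traj.y[k + 1], mean, p.D * dt)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_scaling_d_by_four_with_zero_residuals(self):
        """Pure normalizer algebra: log-lik drops by (N-1) log 4 in 2-D."""
        p = _params(b=(1.0, 0.7), d=(0.5, 0.4))
        n, dt = 30, 0.04
        y = np.empty((n, 2))
        y[0] = [0.5, -0.5]
        for k in range(n - 1):  # exactly follow the drift: residuals are zero
            y[k + 1] = y[k] + p.B @ (p.U - y[k]) * dt
        traj = Trajectory(t=np.arange(n) * dt, y=y)
        p4 = OUParams(p.U, p.B, 4 * p.D, p.R)
        diff = log_likelihood(traj, p4) - log_likelihood(traj, p)
        assert diff == pytest.approx(-(n - 1) * np.log(4), abs=1e-9)

    def test_singular_diffusion_raises(self, short_trajectory):
        p = OUParams(U=[0, 0], B=np.eye(2), D=np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            log_likelihood(short_trajectory, p)

    def test_kalman_with_zero_obs_noise_equals_euler_plus_initial_term(self):
        """With R = 0 the latent state is observed, so the exact likelihood
        is the transition product plus the stationary density of y0."""
        p = _params(u=(0.1, 0.0), b=(1.5, 1.0), rho_b=0.2, d=(0.5, 0.4), rho_d=0.1)
        traj = simulate(p, 40, 0.04, seed=5)
        kal = log_likelihood(traj, p, kernel="kalman")
        eul = log_likelihood(traj, p, kernel="euler")
        init = multivariate_normal.logpdf(traj.y[0], p.U, p.stationary_cov())
        assert kal == pytest.approx(eul + init, abs=1e-8)


class TestFit:
    def test_recovery_on_moderate_trajectory(self, ou_true_params):
        traj = simulate(ou_true_params, 4000, 0.04, seed=21)
        res = OUModel(traj).fit(draws=500, seed=0)
        assert res.diagnostics["converged"]
        idx = [0, 1, 2, 4, 5, 7]  # U, diag B, diag D
        rel = np.abs(
            (res.descriptor() - ou_true_params.descriptor) / ou_true_params.descriptor
        )
        assert (rel[idx] < 0.25).all()

    def test_posterior_draws_satisfy_constraints(self, fitted_ou):
        d = fitted_ou.draws
        assert (d["B_AA"] > 0).all() and (d["B_VV"] > 0).all()
        assert (d["D_AA"] > 0).all() and (d["D_VV"] > 0).all()
        assert (d["rho_B"].abs() < 1).all() and (d["rho_D"].abs() < 1).all()
        # B symmetric with |rho|<1 and positive diagonal => positive eigenvalues
        for _, row in d.sample(50, random_state=0).iterrows():
            B = np.array([[row.B_AA, row.B_AV], [row.B_AV, row.B_VV]])
            assert np.linalg.eigvalsh(B).min() > 0

    def test_longer_trajectory_tightens_home_base_posterior(self, ou_true_params):
        sds_short, sds_long = [], []
        for rep in range(4):
            t1 = simulate(ou_true_params, 1000, 0.04, seed=100 + rep)
            t2 = simulate(ou_true_params, 4000, 0.04, seed=200 + rep)
            sds_short.append(OUModel(t1).fit(draws=400, seed=rep).draws["U_A"].std())
            sds_long.append(OUModel(t2).fit(draws=400, seed=rep).draws["U_A"].std())
        assert np.mean(sds_long) < np.mean(sds_short)

    def test_emcee_agrees_with_laplace(self, ou_true_params):
        """Independent MCMC route reproduces the Laplace posterior means."""
        traj = simulate(ou_true_params, 800, 0.04, seed=3)
        lap = OUModel(traj).fit(draws=500, seed=0)
        mc = OUModel(traj).fit(method="emcee", draws=500, seed=0, nsteps=1200)
        assert np.allclose(lap.descriptor(), mc.descriptor(), rtol=0.2, atol=0.03)


class TestDescriptor:
    def test_single_draw_descriptor_equals_that_draw(self, fitted_ou):
        one = OUResults(
            model=fitted_ou.model, draws=fitted_ou.draws.iloc[[3]], diagnostics={}
        )
        expected = fitted_ou.draws.iloc[3][list(DESCRIPTOR_LABELS)].to_numpy(float)
        assert np.array_equal(one.descriptor(), expected)

    def test_ordering_and_symmetry(self, fitted_ou):
        """Descriptor carries B_AV once (symmetric B), in the fixed order."""
        assert DESCRIPTOR_LABELS == (
            "U_A", "U_V", "B_AA", "B_AV", "B_VV", "D_AA", "D_AV", "D_VV"
        )
        p = fitted_ou.params_at(0)
        assert p.B[0, 1] == p.B[1, 0]

    def test_draws_frame_roundtrip(self):
        x = np.array([[0.1, -0.2, np.log(2.0), np.log(1.5), np.arctanh(0.3),
                       np.log(0.5), np.log(0.4), np.arctanh(-0.2),
                       np.log(0.05), np.log(0.07)]])
        df = _draws_frame(x)
        assert df["B_AA"].iloc[0] == pytest.approx(2.0)
        assert df["B_AV"].iloc[0] == pytest.approx(0.3 * np.sqrt(3.0))
        assert df["D_AA"].iloc[0] == pytest.approx(0.25)
        assert df["D_AV"].iloc[0] == pytest.approx(-0.2 * 0.5 * 0.4)
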