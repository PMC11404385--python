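"""Binary-outcome EM: quadrature, likelihood oracle, gradient, Armijo, fits."""

import numpy as np
import pytest
from scipy import stats
from conftest import align_signs, draw_from_params
from glmpo2pls._gaussian import LowRankNormal, loading_factor
from glmpo2pls.em_binary import (BetaState, _PosteriorCore,
                                 backtracking_update, bernoulli_conditional,
                                 e_step_binary, fit_binary,
                                 gauss_hermite_grid, grad_Q_beta,
                                 loglik_binary)
from glmpo2pls.params import ModelDims, ModelParams
from glmpo2pls.simulate import SimScenario, simulate_dataset


def _toy_binary_params(seed=3):
    """Tiny K=1, p=q=2 bernoulli model for dense-integration oracles."""
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.standard_normal((2, 1)))[0]
    C = np.linalg.qr(rng.standard_normal((2, 1)))[0]
    Wp = np.linalg.qr(rng.standard_normal((2, 1)))[0]
    Cp = np.linalg.qr(rng.standard_normal((2, 1)))[0]
    return ModelParams(W=W, C=C, Wperp=Wp, Cperp=Cp, B=np.ones(1),
                       sigma_t=np.ones(1), sigma_tperp=np.ones(1),
                       sigma_uperp=np.ones(1), sigma_h=np.array([0.7]),
                       sigma_e2=0.3, sigma_f2=0.4, family="bernoulli",
                       a0=0.2, a=np.array([1.2]), b=np.array([0.8]))


def _dense_marginal(params, x_i, y_i, z_i, lim=7.0, n=401):
    """Trapezoid integration of p(z|nu) f(x|nu) f(y|nu) f(nu) over (t, u)."""
    t = np.linspace(-lim, lim, n)
    u = np.linspace(-lim, lim, n)
    T, U = np.meshgrid(t, u, indexing="ij")
    nu = np.stack([T.ravel(), U.ravel()], axis=1)
    Sx = (params.Wperp * params.sigma_tperp) @ params.Wperp.T \
        + params.sigma_e2 * np.eye(2)
    Sy = (params.Cperp * params.sigma_uperp) @ params.Cperp.T \
        + params.sigma_f2 * np.eye(2)
    st, B, sh = params.sigma_t[0], params.B[0], params.sigma_h[0]
    Snu = np.array([[st, st * B], [st * B, B * st * B + sh]])
    fx = stats.multivariate_normal(np.zeros(2), Sx).pdf(
        x_i - nu[:, :1] * params.W.T)
    fy = stats.multivariate_normal(np.zeros(2), Sy).pdf(
        y_i - nu[:, 1:] * params.C.T)
    fnu = stats.multivariate_normal(np.zeros(2), Snu).pdf(nu)
    pz = bernoulli_conditional(np.float64(z_i), nu,
                               np.array([params.a0, params.a[0], params.b[0]]),
                               params.B)
    integ = (pz * fx * fy * fnu).reshape(n, n)
    dt = t[1] - t[0]
    f = np.trapezoid(np.trapezoid(integ, dx=dt, axis=1), dx=dt)
    m_t = np.trapezoid(np.trapezoid(integ * T, dx=dt, axis=1), dx=dt) / f
    m_u = np.trapezoid(np.trapezoid(integ * U, dx=dt, axis=1), dx=dt) / f
    m_tt = np.trapezoid(np.trapezoid(integ * T * T, dx=dt, axis=1), dx=dt) / f
    m_tu = np.trapezoid(np.trapezoid(integ * T * U, dx=dt, axis=1), dx=dt) / f
    m_uu = np.trapezoid(np.trapezoid(integ * U * U, dx=dt, axis=1), dx=dt) / f
    return f, np.array([m_t, m_u]), np.array([[m_tt, m_tu], [m_tu, m_uu]])


class TestQuadratureGrid:
    def test_constant_integrates_to_one(self):
        grid = gauss_hermite_grid(8, np.array([[2.0, 0.5], [0.5, 1.0]]))
        assert np.exp(grid.log_weights).sum() == pytest.approx(1.0, abs=1e-10)

    def test_gaussian_moments(self, rng):
        A = rng.standard_normal((2, 2))
        S = A @ A.T + 0.5 * np.eye(2)
        grid = gauss_hermite_grid(8, S)
        mean = grid.integrate(grid.nodes)
        second = grid.integrate(np.einsum("mj,mk->mjk", grid.nodes, grid.nodes))
        assert np.abs(mean).max() < 1e-8
        assert np.abs(second - S).max() < 1e-8

    def test_two_point_nodes_at_unit(self):
        """M=2 standard Hermite nodes +-1/sqrt(2) map to +-1 for identity cov."""
        grid = gauss_hermite_grid(2, np.eye(2))
        assert np.allclose(np.sort(np.unique(np.round(grid.nodes, 12))),
                           [-1.0, 1.0])

    def test_not_psd_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            gauss_hermite_grid(4, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestBernoulliConditional:
    def test_half_at_zero_beta(self, rng):
        nu = rng.standard_normal((5, 2))
        p1 = bernoulli_conditional(1.0, nu, np.zeros(3), np.ones(1))
        p0 = bernoulli_conditional(0.0, nu, np.zeros(3), np.ones(1))
        assert np.allclose(p1, 0.5) and np.allclose(p0, 0.5)

    def test_normalization(self, rng):
        nu = rng.standard_normal((20, 2))
        beta = rng.standard_normal(3)
        p1 = bernoulli_conditional(1.0, nu, beta, np.array([0.7]))
        p0 = bernoulli_conditional(0.0, nu, beta, np.array([0.7]))
        assert np.allclose(p1 + p0, 1.0)

    def test_extreme_predictor_stable(self):
        nu = np.array([[40.0, 0.0]])
        p = bernoulli_conditional(1.0, nu, np.array([0.0, 1.0, 0.0]),
                                  np.ones(1))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestLoglikBinary:
    def test_zero_beta_factorizes(self):
        """With beta = 0, ll = log f(x, y) + N log(1/2)."""
        params = _toy_binary_params()
        params.a0, params.a, params.b = 0.0, np.zeros(1), np.zeros(1)
        rng = np.random.default_rng(8)
        x, y, z, _ = draw_from_params(params, 50, rng)
        ll = loglik_binary(params, x, y, z, M=8)
        lr = LowRankNormal(*loading_factor(params, include_z=False))
        expected = lr.loglik(np.hstack([x, y])) + 50 * np.log(0.5)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_grid_oracle(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(4)
        x, y, z, _ = draw_from_params(params, 6, rng)
        ll = loglik_binary(params, x, y, z, M=16)
        dense = sum(np.log(_dense_marginal(params, x[i], y[i], z[i])[0])
                    for i in range(6))
        assert ll == pytest.approx(dense, abs=1e-6)

    def test_quadrature_m_convergence(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(5)
        x, y, z, _ = draw_from_params(params, 30, rng)
        ll8 = loglik_binary(params, x, y, z, M=8)
        ll16 = loglik_binary(params, x, y, z, M=16)
        assert abs(ll16 - ll8) < 1e-6


class TestEStepBinary:
    def test_moments_match_dense_grid_oracle(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(14)
        x, y, z, _ = draw_from_params(params, 5, rng)
        mom, logf = e_step_binary(params, x, y, z, M=16)
        for i in range(5):
            f, m1, m2 = _dense_marginal(params, x[i], y[i], z[i])
            assert np.abs(mom.nu_mean[i] - m1).max() < 1e-5
            assert np.abs(mom.nu_second[i] - m2).max() < 1e-5
            assert logf[i] == pytest.approx(np.log(f), abs=1e-6)

    def test_zero_beta_equals_xy_conditioning(self):
        """z is uninformative at beta = 0: moments = Gaussian conditioning."""
        params = _toy_binary_params()
        params.a0, params.a, params.b = 0.0, np.zeros(1), np.zeros(1)
        rng = np.random.default_rng(2)
        x, y, z, _ = draw_from_params(params, 40, rng)
        mom, _ = e_step_binary(params, x, y, z, M=8)
        lr = LowRankNormal(*loading_factor(params, include_z=False))
        m0 = lr.posterior_mean(np.hstack([x, y]))
        t, u = m0[:, 0], m0[:, 0] * params.B[0] + m0[:, 1]
        assert np.abs(mom.nu_mean[:, 0] - t).max() < 1e-10
        assert np.abs(mom.nu_mean[:, 1] - u).max() < 1e-10

    def test_conditional_covariance_psd(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(6)
        x, y, z, _ = draw_from_params(params, 30, rng)
        mom, _ = e_step_binary(params, x, y, z, M=8)
        cond = mom.nu_second - np.einsum("ij,ik->ijk", mom.nu_mean,
                                         mom.nu_mean)
        assert np.linalg.eigvalsh(cond).min() > -1e-10

    def test_doubling_m_stabilizes_moments(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(16)
        x, y, z, _ = draw_from_params(params, 30, rng)
        m8, _ = e_step_binary(params, x, y, z, M=8)
        m16, _ = e_step_binary(params, x, y, z, M=16)
        assert np.abs(m8.nu_mean - m16.nu_mean).max() < 1e-5
        assert np.abs(m8.nu_second - m16.nu_second).max() < 1e-5


class TestGradQBeta:
    def test_matches_central_differences(self):
        params = _toy_binary_params()
        rng = np.random.default_rng(9)
        x, y, z, _ = draw_from_params(params, 25, rng)
        core = _PosteriorCore(params, x, y, z, 12)
        beta = np.array([0.1, 0.6, -0.4])
        grad = grad_Q_beta(params, x, y, z, beta, M=12)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (core.q_beta(beta + e) - core.q_beta(beta - e)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-5)

    def test_zero_gradient_at_q_maximizer(self):
        from scipy.optimize import minimize
        params = _toy_binary_params()
        rng = np.random.default_rng(10)
        x, y, z, _ = draw_from_params(params, 40, rng)
        core = _PosteriorCore(params, x, y, z, 12)
        res = minimize(lambda b: -core.q_beta(b), np.zeros(3),
                       jac=lambda b: -core.grad_q_beta(b), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.linalg.norm(core.grad_q_beta(res.x)) < 1e-6

    def test_balanced_symmetric_data_zero_intercept_gradient(self):
        params = _toy_binary_params()
        params.a0 = 0.0
        rng = np.random.default_rng(11)
        x, y, z, _ = draw_from_params(params, 30, rng)
        # mirrored data with complemented outcomes: intercept score cancels
        X = np.vstack([x, -x])
        Y = np.vstack([y, -y])
        Z = np.concatenate([z, 1 - z])
        grad = grad_Q_beta(params, X, Y, Z,
                           np.array([0.0, params.a[0], params.b[0]]), M=8)
        assert abs(grad[0]) < 1e-8


class TestBacktracking:
    def test_zero_gradient_no_move(self):
        st = BetaState(beta=np.array([1.0, 2.0]), grad=np.zeros(2))
        out = backtracking_update(st, lambda b: 0.0)
        assert np.array_equal(out.beta, st.beta) and out.step == 1.0

    def test_concave_quadratic_satisfies_armijo(self):
        q = lambda b: -0.5 * float(b @ b)
        beta = np.array([1.0, 0.0])
        st = BetaState(beta=beta, grad=-beta)   # gradient of q at beta
        out = backtracking_update(st, q)
        g2 = float(beta @ beta)
        assert q(out.beta) >= q(beta) + 0.5 * out.step * g2
        assert out.step == 1.0   # s=1 already satisfies the condition

    def test_linear_q_accepts_full_step(self):
        c = np.array([0.3, -0.7])
        st = BetaState(beta=np.zeros(2), grad=c)
        out = backtracking_update(st, lambda b: float(c @ b))
        assert out.step == 1.0
        assert np.allclose(out.beta, c)

    def test_needs_shrinking_on_sharp_quadratic(self):
        # q(b) = -5 b^2: full step overshoots, Armijo shrinks
        q = lambda b: -5.0 * float(b @ b)
        beta = np.array([1.0])
        st = BetaState(beta=beta, grad=np.array([-10.0]))
        out = backtracking_update(st, q)
        assert out.step < 1.0
        assert q(out.beta) >= q(beta) + 0.5 * out.step * 100.0


class TestFitBinary:
    def test_recovery_sign_correct(self):
        sc = SimScenario(N=500, p=100, q=10, family="bernoulli", seed=11)
        x, y, z, _, truth = simulate_dataset(sc)
        fit = fit_binary(x, y, z, ModelDims(p=100, q=10, K=1, Kx=1, Ky=1))
        est = align_signs(fit.params, truth)
        assert est.a[0] > 0 and est.b[0] > 0
        assert abs((est.a[0] - 2.0) / 2.0) < 0.5
        assert abs((est.b[0] - 1.0) / 1.0) < 0.5

    def test_loglik_trace_nondecreasing(self):
        sc = SimScenario(N=200, p=20, q=8, family="bernoulli", seed=23)
        x, y, z, *_ = simulate_dataset(sc)
        fit = fit_binary(x, y, z, ModelDims(p=20, q=8, K=1, Kx=1, Ky=1), M=8)
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() >= -1e-6 * np.abs(fit.loglik_trace).max()

    def test_degenerate_outcome_raises(self):
        sc = SimScenario(N=50, p=10, q=5, seed=1)
        x, y, *_ = simulate_dataset(sc)
        with pytest.raises(ValueError, match="separation"):
            fit_binary(x, y, np.ones(50), ModelDims(p=10, q=5, K=1, Kx=1, Ky=1))

    def test_miscoded_outcome_raises(self):
        sc = SimScenario(N=50, p=10, q=5, seed=1)
        x, y, *_ = simulate_dataset(sc)
        z = np.zeros(50)
        z[::2] = 2.0
        with pytest.raises(ValueError, match="0/1"):
            fit_binary(x, y, z, ModelDims(p=10, q=5, K=1, Kx=1, Ky=1))

    def test_grid_budget_guard(self):
        sc = SimScenario(N=60, p=12, q=8, K=3, seed=2, family="bernoulli")
        x, y, z, *_ = simulate_dataset(sc)
        with pytest.raises(ValueError, match="grid"):
            fit_binary(x, y, z, ModelDims(p=12, q=8, K=3, Kx=1, Ky=1), M=16)
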