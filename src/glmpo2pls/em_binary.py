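"""EM estimation for the bernoulli-outcome model.

The observed-data likelihood integrates the joint latents nu = (t, u); the
block-specific latents xi = (t_perp, u_perp) are integrated out analytically.
The remaining 2K-dimensional integral is evaluated by factorizing

    p(z|nu) f(x,y|nu) f(nu)  =  f(x,y) * p(z|nu) f(nu|x,y),

where f(nu|x,y) is Gaussian with a mean and covariance available in closed
form through the low-rank conditioning machinery.  A tensor-product
Gauss-Hermite rule (nodes transformed by sqrt(2) * Sigma^(1/2), product
weights normalized by pi^(-K) so the Gaussian density integrates to one) is
applied to this conditional Gaussian; only the smooth logistic factor
p(z|nu) is left to the quadrature, so a modest M per dimension is accurate
at any data dimensionality.  Scaling the rule by the prior Cov(nu) instead
concentrates the posterior mass between nodes once the omics blocks are
informative, quantizing the E-step moments and destroying the EM ascent;
see docs/methods.md.

The outcome coefficients beta = (a0, a, b) have no closed-form update; each
EM iteration takes one gradient-ascent step on Q_beta with an Armijo
backtracking step size (start 1, shrink by 0.8 until
Q(beta + s g) >= Q(beta) + 0.5 s |g|^2).  All other parameters reuse the
closed-form Gaussian updates of the normal-outcome M-step, with the xi
statistics recovered by Gaussian conditioning of xi given (nu, x, y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import expit, logsumexp

from ._gaussian import LowRankNormal, loading_factor
from .em_normal import (LatentMoments, _center, _zeta_map, initialize_params,
                        m_step_po2pls_block)
from .params import ModelDims, ModelParams, canonicalize_signs, sort_components
from .results import FitResult

GRID_HARD_LIMIT = 1_000_000
GRID_WARN_LIMIT = 50_000


@dataclass
class QuadratureGrid:
    """Tensor-product Gauss-Hermite grid adapted to nu ~ N(0, Sigma_nu)."""

    M: int
    nodes: np.ndarray        # M^d x d, transformed node vectors
    log_weights: np.ndarray  # M^d, log of normalized product weights
    Sigma_nu: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Integral of phi(nu) against the N(0, Sigma_nu) density.

        ``values`` holds phi evaluated at the grid nodes along its first axis.
        """
        w = np.exp(self.log_weights)
        return np.tensordot(w, values, axes=(0, 0))


def gauss_hermite_grid(M: int, Sigma_nu: np.ndarray) -> QuadratureGrid:
    """Build the transformed tensor-product rule for a d-dimensional Gaussian."""
    if M < 2:
        raise ValueError("at least 2 quadrature nodes per dimension required")
    Sigma_nu = np.asarray(Sigma_nu, float)
    d = Sigma_nu.shape[0]
    try:
        Lc = np.linalg.cholesky(Sigma_nu)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"Sigma_nu is not positive definite: {exc}")
    n1, w1 = np.polynomial.hermite.hermgauss(M)
    idx = np.stack(np.meshgrid(*([np.arange(M)] * d), indexing="ij"),
                   axis=-1).reshape(-1, d)
    std_nodes = n1[idx]
    log_weights = np.log(w1)[idx].sum(axis=1) - 0.5 * d * np.log(np.pi)
    nodes = np.sqrt(2.0) * std_nodes @ Lc.T
    return QuadratureGrid(M=M, nodes=nodes, log_weights=log_weights,
                          Sigma_nu=Sigma_nu)


def _design(nu: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Outcome design (1, t, u - tB) for rows nu = (t, u)."""
    nu = np.atleast_2d(np.asarray(nu, float))
    K = nu.shape[1] // 2
    t, u = nu[:, :K], nu[:, K:]
    return np.hstack([np.ones((nu.shape[0], 1)), t, u - t * B])


def log_bernoulli_conditional(z, nu, beta: np.ndarray, B: np.ndarray) -> np.ndarray:
    """log p(z | nu) = z * eta - log(1 + exp(eta)), numerically stable."""
    eta = _design(nu, B) @ np.asarray(beta, float)
    z = np.asarray(z, float)
    if z.ndim == 0:
        return z * eta - np.logaddexp(0.0, eta)
    return z[:, None] * eta[None, :] - np.logaddexp(0.0, eta)[None, :]


def bernoulli_conditional(z, nu, beta: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Probability mass p(z | nu) under the logistic outcome model."""
    return np.exp(log_bernoulli_conditional(z, nu, beta, B))


def _resolve_M(M) -> int:
    return M.M if isinstance(M, QuadratureGrid) else int(M)


class _PosteriorCore:
    """One quadrature E-step: posterior of (t, u, tp, up) given (x, y, z).

    Conditions the full latent vector on (x, y) exactly, then tilts the
    (t, u) block by the logistic outcome factor on a Gauss-Hermite grid
    scaled to Cov(nu | x, y).
    """

    def __init__(self, params: ModelParams, x, y, z, M: int = 16):
        z = np.asarray(z, float).reshape(-1)
        d = params.dims
        K = d.K
        lr = LowRankNormal(*loading_factor(params, include_z=False))
        psi = np.hstack([x, y])
        mean0, logf_xy = lr.posterior_mean_and_logpdf(psi)
        T = _zeta_map(params)
        mz = mean0 @ T.T                       # E[zeta | x, y], zeta=(t,u,tp,up)
        Vz = T @ lr.posterior_cov @ T.T
        m_nu, V_nu = mz[:, :2 * K], Vz[:2 * K, :2 * K]

        grid = gauss_hermite_grid(M, V_nu)
        delta = grid.nodes                     # n_nodes x 2K offsets
        w_eta = np.concatenate([params.a - params.B * params.b, params.b])
        eta = (params.a0 + m_nu @ w_eta)[:, None] + (delta @ w_eta)[None, :]
        logp = z[:, None] * eta - np.logaddexp(0.0, eta)
        log_tilt = logsumexp(grid.log_weights[None, :] + logp, axis=1)
        self.logf = logf_xy + log_tilt
        self.omega = np.exp(grid.log_weights[None, :] + logp
                            - log_tilt[:, None])

        ED = self.omega @ delta
        EDD = np.einsum("im,mj,mk->ijk", self.omega, delta, delta)
        self.nu_mean = m_nu + ED
        self.nu_second = (np.einsum("ij,ik->ijk", m_nu, m_nu)
                          + np.einsum("ij,ik->ijk", m_nu, ED)
                          + np.einsum("ij,ik->ijk", ED, m_nu)
                          + EDD)
        # designs (1, t, h) split into per-subject and per-node parts
        m_h = m_nu[:, K:] - m_nu[:, :K] * params.B
        d_h = delta[:, K:] - delta[:, :K] * params.B
        self.d0 = np.hstack([np.ones((len(z), 1)), m_nu[:, :K], m_h])
        self.dD = np.hstack([np.zeros((delta.shape[0], 1)), delta[:, :K], d_h])
        self.z = z
        self.grid = grid
        self._xi = (mz, Vz, K, d.Kx)

    def moments(self, params: ModelParams, x, y) -> LatentMoments:
        """Aggregated sufficient statistics for the M-step."""
        mz, Vz, K, Kx = self._xi
        n = self.nu_mean.shape[0]
        # xi = (tp, up) given (nu, x, y): linear in nu with constant covariance
        V_nn = Vz[:2 * K, :2 * K]
        V_xn = Vz[2 * K:, :2 * K]
        R = linalg.solve(V_nn, V_xn.T, assume_a="pos").T   # (Kx+Ky) x 2K
        cov_xi = Vz[2 * K:, 2 * K:] - R @ V_xn.T
        c_xi = mz[:, 2 * K:] - mz[:, :2 * K] @ R.T          # N x (Kx+Ky)
        xi_mean = c_xi + self.nu_mean @ R.T
        S_nu = self.nu_second.sum(axis=0)
        sum_nu = self.nu_mean.sum(axis=0)
        # sum_i E[nu' xi] = sum_i (E[nu]' c_xi + E[nu'nu] R')
        S_nu_xi = self.nu_mean.T @ c_xi + S_nu @ R.T
        S_xi = (n * cov_xi
                + c_xi.T @ c_xi + c_xi.T @ (self.nu_mean @ R.T)
                + (self.nu_mean @ R.T).T @ c_xi + R @ S_nu @ R.T)
        sl_t, sl_u = slice(0, K), slice(K, 2 * K)
        sl_tp, sl_up = slice(0, Kx), slice(Kx, None)
        return LatentMoments(
            n=n, B_estep=params.B.copy(),
            nu_mean=self.nu_mean, nu_second=self.nu_second,
            S_ttp=S_nu_xi[sl_t, sl_tp], S_tptp=S_xi[sl_tp, sl_tp],
            S_uup=S_nu_xi[sl_u, sl_up], S_upup=S_xi[sl_up, sl_up],
            Mx_t=x.T @ self.nu_mean[:, sl_t], Mx_tp=x.T @ xi_mean[:, sl_tp],
            My_u=y.T @ self.nu_mean[:, sl_u], My_up=y.T @ xi_mean[:, sl_up],
            Szt=self.z @ self.nu_mean[:, sl_t],
            Szu=self.z @ self.nu_mean[:, sl_u],
            Sxx=float((x * x).sum()), Syy=float((y * y).sum()),
            Szz=float(self.z @ self.z), loglik=float(self.logf.sum()),
        )

    # --- Q_beta machinery -------------------------------------------------
    def _eta(self, beta: np.ndarray) -> np.ndarray:
        return (self.d0 @ beta)[:, None] + (self.dD @ beta)[None, :]

    def q_beta(self, beta: np.ndarray) -> float:
        eta = self._eta(beta)
        return float((self.omega * (self.z[:, None] * eta
                                    - np.logaddexp(0.0, eta))).sum())

    def grad_q_beta(self, beta: np.ndarray) -> np.ndarray:
        ws = self.omega * (self.z[:, None] - expit(self._eta(beta)))
        return self.d0.T @ ws.sum(axis=1) + self.dD.T @ ws.sum(axis=0)


def loglik_binary(params: ModelParams, x, y, z, M=16) -> float:
    """Quadrature approximation of the observed-data log-likelihood.

    ``M`` is the number of Gauss-Hermite nodes per dimension (a
    QuadratureGrid may be passed as a template for its M).
    """
    return float(_PosteriorCore(params, x, y, z, _resolve_M(M)).logf.sum())


def e_step_binary(params: ModelParams, x, y, z, M=16):
    """Quadrature conditional moments; returns (LatentMoments, log f(x,y,z))."""
    core = _PosteriorCore(params, x, y, z, _resolve_M(M))
    return core.moments(params, x, y), core.logf


def grad_Q_beta(params: ModelParams, x, y, z, beta: np.ndarray, M=16) -> np.ndarray:
    """Gradient of Q_beta at ``beta``, posterior weights at ``params``."""
    core = _PosteriorCore(params, x, y, z, _resolve_M(M))
    return core.grad_q_beta(np.asarray(beta, float))


@dataclass
class BetaState:
    """Linear-predictor coefficients (a0, a, b) plus line-search bookkeeping."""

    beta: np.ndarray
    step: float = 1.0
    grad: np.ndarray | None = None


def backtracking_update(state: BetaState, q_fun, shrink: float = 0.8,
                        c: float = 0.5, min_step: float = 1e-12) -> BetaState:
    """One gradient-ascent step with the Armijo backtracking rule.

    Accepts the first s in {1, shrink, shrink^2, ...} with
    q(beta + s g) >= q(beta) + c * s * |g|^2; if s underflows ``min_step``
    the update is skipped with a warning (flat region).
    """
    g = state.grad
    gnorm2 = float(g @ g)
    if gnorm2 == 0.0:
        return BetaState(beta=state.beta.copy(), step=1.0, grad=g)
    q0 = q_fun(state.beta)
    s = 1.0
    while s >= min_step:
        cand = state.beta + s * g
        if q_fun(cand) >= q0 + c * s * gnorm2:
            return BetaState(beta=cand, step=s, grad=g)
        s *= shrink
    warnings.warn("backtracking step size underflow; beta update skipped",
                  RuntimeWarning)
    return BetaState(beta=state.beta.copy(), step=min_step, grad=g)


def fit_binary(x, y, z, dims: ModelDims, M: int = 16, tol: float = 1e-6,
               max_iter: int = 2000, init_params: ModelParams | None = None,
               seed=None) -> FitResult:
    """Maximum-likelihood fit of the bernoulli-outcome model.

    Generalized EM: quadrature E-step over nu = (t, u), one Armijo gradient
    step for beta = (a0, a, b), closed-form updates for the Gaussian blocks.
    The quadrature log-likelihood trace is non-decreasing up to quadrature
    error.
    """
    z = np.asarray(z, float).reshape(-1)
    if not set(np.unique(z)) <= {0.0, 1.0}:
        raise ValueError("bernoulli outcome must be coded 0/1")
    if z.min() == z.max():
        raise ValueError("outcome has no variation (complete separation); "
                         "the intercept diverges and the model cannot be fit")
    n_grid = M ** (2 * dims.K)
    if n_grid > GRID_HARD_LIMIT:
        raise ValueError(
            f"quadrature grid would need M^(2K) = {n_grid} points; reduce the "
            "number of joint components K or the nodes per dimension M")
    if n_grid > GRID_WARN_LIMIT:
        warnings.warn(f"large quadrature grid ({n_grid} points); expect slow "
                      "iterations", RuntimeWarning)

    x, y, z, xm, ym, _ = _center(x, y, z, center_z=False)
    n = x.shape[0]
    if n <= dims.K + dims.Kx + dims.Ky:
        raise ValueError("sample size must exceed the total component count")
    params = init_params.copy() if init_params is not None else \
        initialize_params(x, y, z, dims, family="bernoulli", seed=seed)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(max_iter + 1):
        core = _PosteriorCore(params, x, y, z, M)
        trace.append(float(core.logf.sum()))
        if it > 0:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
            if not rel >= tol:
                converged = True
                break
        if it == max_iter:
            break
        moments = core.moments(params, x, y)
        beta = np.concatenate([[params.a0], params.a, params.b])
        state = BetaState(beta=beta, grad=core.grad_q_beta(beta))
        state = backtracking_update(state, core.q_beta)
        block = m_step_po2pls_block(moments, params)
        K = dims.K
        params = ModelParams(family="bernoulli", a0=float(state.beta[0]),
                             a=state.beta[1:K + 1], b=state.beta[K + 1:],
                             sigma_g2=None, **block)
        n_iter = it + 1
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning the "
                      "last iterate", RuntimeWarning)
    params = canonicalize_signs(sort_components(params))
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=n_iter, converged=converged, tol_used=tol,
                     x_mean=xm, y_mean=ym, z_mean=0.0)
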