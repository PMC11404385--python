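"""EM estimation for the gaussian-outcome model.

The complete-data log-likelihood factorizes into per-term Gaussian densities
f(z|t,h) f(x|t,tp) f(y|u,up) f(u|t) f(t) f(tp) f(up), each maximized in
closed form given the conditional latent moments.  The outcome block has the
closed form (a, b) = z'E[(t,h)] (E[(t,h)'(t,h)])^-1; loading blocks are
maximized under the semi-orthogonality constraint by polar projection (the
quadratic term is constant on the Stiefel manifold, so the polar factor is
the exact constrained maximizer given the other block), which preserves the
EM ascent property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.utils.extmath import randomized_svd

from ._gaussian import LowRankNormal, loading_factor
from .params import ModelDims, ModelParams, canonicalize_signs, sort_components
from .results import FitResult

_VAR_FLOOR = 1e-10


@dataclass
class LatentMoments:
    """Conditional latent moments and aggregated sufficient statistics.

    Per-subject first/second moments are kept for nu = (t, u) (used by the
    inference module); everything the M-step needs is aggregated over
    subjects, including the data cross-products.  ``B_estep`` is the B at
    which the moments were computed, defining h = u - tB.
    """

    n: int
    B_estep: np.ndarray
    nu_mean: np.ndarray        # N x 2K
    nu_second: np.ndarray      # N x 2K x 2K, E[nu'nu | data]
    S_ttp: np.ndarray          # sum_i E[t' tperp]
    S_tptp: np.ndarray
    S_uup: np.ndarray
    S_upup: np.ndarray
    Mx_t: np.ndarray           # x' E[T]
    Mx_tp: np.ndarray
    My_u: np.ndarray
    My_up: np.ndarray
    Szt: np.ndarray            # z' E[T]
    Szu: np.ndarray
    Sxx: float
    Syy: float
    Szz: float
    loglik: float              # observed-data log-likelihood at theta'

    @property
    def K(self) -> int:
        return self.nu_mean.shape[1] // 2

    @property
    def S_nu(self) -> np.ndarray:
        """sum_i E[(t,u)'(t,u) | data_i], a 2K x 2K matrix."""
        return self.nu_second.sum(axis=0)

    def th_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Aggregated moments in the v = (t, h) basis: (S_vv, z'E[v])."""
        K, B = self.K, self.B_estep
        A = np.eye(2 * K)
        A[K:, :K] = -np.diag(B)
        S_vv = A @ self.S_nu @ A.T
        Szv = np.concatenate([self.Szt, self.Szu - self.Szt * B])
        return S_vv, Szv

    def h_mean(self) -> np.ndarray:
        """E[h | data] = E[u | data] - E[t | data] B, per subject."""
        K = self.K
        return self.nu_mean[:, K:] - self.nu_mean[:, :K] * self.B_estep


def _zeta_map(params: ModelParams) -> np.ndarray:
    """Linear map from zeta0 = (t, h, tp, up) to zeta = (t, u, tp, up)."""
    d = params.dims
    K, dd = d.K, 2 * d.K + d.Kx + d.Ky
    T = np.eye(dd)
    T[K:2 * K, :K] = np.diag(params.B)
    return T


def _aggregate(params, x, y, z, mean0, cov0, loglik) -> LatentMoments:
    d = params.dims
    K, Kx = d.K, d.Kx
    T = _zeta_map(params)
    means = mean0 @ T.T
    cov = T @ cov0 @ T.T
    n = x.shape[0]
    S = means.T @ means + n * cov

    nu_mean = means[:, :2 * K]
    nu_second = (np.einsum("ij,ik->ijk", nu_mean, nu_mean)
                 + cov[:2 * K, :2 * K])
    sl_t, sl_u = slice(0, K), slice(K, 2 * K)
    sl_tp, sl_up = slice(2 * K, 2 * K + Kx), slice(2 * K + Kx, None)
    return LatentMoments(
        n=n, B_estep=params.B.copy(),
        nu_mean=nu_mean, nu_second=nu_second,
        S_ttp=S[sl_t, sl_tp], S_tptp=S[sl_tp, sl_tp],
        S_uup=S[sl_u, sl_up], S_upup=S[sl_up, sl_up],
        Mx_t=x.T @ means[:, sl_t], Mx_tp=x.T @ means[:, sl_tp],
        My_u=y.T @ means[:, sl_u], My_up=y.T @ means[:, sl_up],
        Szt=z @ means[:, sl_t], Szu=z @ means[:, sl_u],
        Sxx=float((x * x).sum()), Syy=float((y * y).sum()),
        Szz=float(z @ z), loglik=loglik,
    )


def loglik_normal(params: ModelParams, x, y, z) -> float:
    """Observed-data log-likelihood, computed through the low-rank factors."""
    lr = LowRankNormal(*loading_factor(params, include_z=True))
    psi = np.hstack([x, y, np.asarray(z, float).reshape(-1, 1)])
    return lr.loglik(psi)


def e_step_normal(params: ModelParams, x, y, z) -> LatentMoments:
    """Exact Gaussian conditional moments of (t, u, tp, up) given (x, y, z)."""
    z = np.asarray(z, float).reshape(-1)
    lr = LowRankNormal(*loading_factor(params, include_z=True))
    psi = np.hstack([x, y, z[:, None]])
    mean0, logpdf = lr.posterior_mean_and_logpdf(psi)
    return _aggregate(params, x, y, z, mean0, lr.posterior_cov,
                      float(logpdf.sum()))


def m_step_outcome_normal(moments: LatentMoments, z) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form update of (a, b, sigma_g2) from the (t, h) moments."""
    S_vv, Szv = moments.th_stats()
    K, n = moments.K, moments.n
    try:
        alpha = linalg.solve(S_vv, Szv, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular latent moment matrix ({exc}); consider fewer joint "
            "components") from exc
    Szz = float(np.asarray(z, float).reshape(-1) @ np.asarray(z, float).reshape(-1))
    sigma_g2 = (Szz - 2.0 * alpha @ Szv + alpha @ S_vv @ alpha) / n
    return alpha[:K], alpha[K:], max(float(sigma_g2), _VAR_FLOOR)


def _polar(M: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Nearest (semi-)orthogonal matrix; falls back if M is numerically zero."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if not np.all(s > 0):
        return fallback
    return U @ Vt


def m_step_po2pls_block(moments: LatentMoments, params: ModelParams) -> dict:
    """Maximizers of the non-outcome factorized Gaussian terms.

    Returns the updated {W, C, Wperp, Cperp, B, sigma_t, sigma_tperp,
    sigma_uperp, sigma_h, sigma_e2, sigma_f2}.  W/Wperp (and C/Cperp) are
    updated in one block-coordinate pass; each polar step is the exact
    constrained maximizer given the other block.
    """
    K = moments.K
    n = moments.n
    p, q = moments.Mx_t.shape[0], moments.My_u.shape[0]
    S_nu = moments.S_nu
    S_tt, S_tu, S_uu = S_nu[:K, :K], S_nu[:K, K:], S_nu[K:, K:]

    W = _polar(moments.Mx_t - params.Wperp @ moments.S_ttp.T, params.W)
    Wperp = _polar(moments.Mx_tp - W @ moments.S_ttp, params.Wperp)
    C = _polar(moments.My_u - params.Cperp @ moments.S_uup.T, params.C)
    Cperp = _polar(moments.My_up - C @ moments.S_uup, params.Cperp)

    B = np.diag(S_tu) / np.diag(S_tt)
    S_hh = (S_uu - B[:, None] * S_tu - S_tu.T * B[None, :]
            + B[:, None] * S_tt * B[None, :])
    sigma_h = np.maximum(np.diag(S_hh) / n, _VAR_FLOOR)
    sigma_t = np.maximum(np.diag(S_tt) / n, _VAR_FLOOR)
    sigma_tperp = np.maximum(np.diag(moments.S_tptp) / n, _VAR_FLOOR)
    sigma_uperp = np.maximum(np.diag(moments.S_upup) / n, _VAR_FLOOR)

    rss_x = (moments.Sxx
             - 2.0 * np.trace(W.T @ moments.Mx_t)
             - 2.0 * np.trace(Wperp.T @ moments.Mx_tp)
             + np.trace(S_tt) + np.trace(moments.S_tptp)
             + 2.0 * np.trace(W.T @ Wperp @ moments.S_ttp.T))
    rss_y = (moments.Syy
             - 2.0 * np.trace(C.T @ moments.My_u)
             - 2.0 * np.trace(Cperp.T @ moments.My_up)
             + np.trace(S_uu) + np.trace(moments.S_upup)
             + 2.0 * np.trace(C.T @ Cperp @ moments.S_uup.T))
    sigma_e2 = max(rss_x / (n * p), _VAR_FLOOR)
    sigma_f2 = max(rss_y / (n * q), _VAR_FLOOR)

    return dict(W=W, C=C, Wperp=Wperp, Cperp=Cperp, B=B,
                sigma_t=sigma_t, sigma_tperp=sigma_tperp,
                sigma_uperp=sigma_uperp, sigma_h=sigma_h,
                sigma_e2=sigma_e2, sigma_f2=sigma_f2)


def _logistic_irls(design: np.ndarray, z: np.ndarray, n_iter: int = 25,
                   ridge: float = 1e-4) -> np.ndarray:
    """Small ridge-stabilized IRLS for initializing (a0, a, b)."""
    beta = np.zeros(design.shape[1])
    for _ in range(n_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = np.maximum(mu * (1.0 - mu), 1e-6)
        H = design.T @ (design * wt[:, None]) + ridge * np.eye(design.shape[1])
        grad = design.T @ (z - mu) - ridge * beta
        step = linalg.solve(H, grad, assume_a="pos")
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def initialize_params(x, y, z, dims: ModelDims, family: str = "gaussian",
                      seed=None) -> ModelParams:
    """Method-of-moments starting values.

    W, C come from the top-K singular triplets of x'y; specific loadings from
    the principal directions of the joint residuals; variances from explained
    -variance splits; B, (a, b) from regressions on the estimated scores.
    If ``seed`` is given the joint loadings are jittered (re-orthogonalized)
    for random restarts.
    """
    rs = 0 if seed is None else int(seed)
    K, Kx, Ky = dims.K, dims.Kx, dims.Ky
    U, _, Vt = randomized_svd(x.T @ y, n_components=K, random_state=rs)
    W, C = U, Vt.T
    if seed is not None:
        rng = np.random.default_rng(seed)
        W = _polar(W + 0.1 * rng.standard_normal(W.shape), W)
        C = _polar(C + 0.1 * rng.standard_normal(C.shape), C)

    t_hat, u_hat = x @ W, y @ C
    Ex = x - t_hat @ W.T
    Ey = y - u_hat @ C.T
    Wperp = randomized_svd(Ex, n_components=Kx, random_state=rs)[2].T
    Cperp = randomized_svd(Ey, n_components=Ky, random_state=rs)[2].T
    tp_hat, up_hat = Ex @ Wperp, Ey @ Cperp

    n = x.shape[0]
    sigma_t = np.maximum((t_hat ** 2).mean(axis=0), _VAR_FLOOR)
    B = (t_hat * u_hat).mean(axis=0) / sigma_t
    B = np.where(np.abs(B) < 1e-3, 1e-3, B)
    h_hat = u_hat - t_hat * B
    sigma_h = np.maximum((h_hat ** 2).mean(axis=0), _VAR_FLOOR)
    sigma_tperp = np.maximum((tp_hat ** 2).mean(axis=0), _VAR_FLOOR)
    sigma_uperp = np.maximum((up_hat ** 2).mean(axis=0), _VAR_FLOOR)
    sigma_e2 = max(((Ex - tp_hat @ Wperp.T) ** 2).mean(), _VAR_FLOOR)
    sigma_f2 = max(((Ey - up_hat @ Cperp.T) ** 2).mean(), _VAR_FLOOR)

    z = np.asarray(z, float).reshape(-1)
    scores = np.hstack([t_hat, h_hat])
    if family == "gaussian":
        alpha = np.linalg.lstsq(scores, z, rcond=None)[0]
        resid = z - scores @ alpha
        sigma_g2 = max(float((resid ** 2).mean()), 1e-6 * max(float(z @ z / n), 1.0))
        a0 = 0.0
    else:
        beta = _logistic_irls(np.hstack([np.ones((n, 1)), scores]), z)
        a0, alpha = float(beta[0]), beta[1:]
        sigma_g2 = None
    return ModelParams(
        W=W, C=C, Wperp=Wperp, Cperp=Cperp, B=B,
        sigma_t=sigma_t, sigma_tperp=sigma_tperp, sigma_uperp=sigma_uperp,
        sigma_h=sigma_h, sigma_e2=sigma_e2, sigma_f2=sigma_f2,
        family=family, a0=a0, a=alpha[:K], b=alpha[K:], sigma_g2=sigma_g2,
    )


def _center(x, y, z, center_z=True):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float).reshape(-1)
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    zm = float(z.mean()) if center_z else 0.0
    return x - xm, y - ym, z - zm, xm, ym, zm


def fit_normal(x, y, z, dims: ModelDims, tol: float = 1e-6,
               max_iter: int = 10_000, init_params: ModelParams | None = None,
               seed=None) -> FitResult:
    """Maximum-likelihood fit of the gaussian-outcome model by EM.

    Data are column-centered internally (z as well); convergence is declared
    when the relative change of the observed-data log-likelihood drops below
    ``tol``.  The returned parameters are sorted by diag(Sigma_t B) and
    sign-canonicalized.
    """
    x, y, z, xm, ym, zm = _center(x, y, z)
    n = x.shape[0]
    if n <= dims.K + dims.Kx + dims.Ky:
        raise ValueError("sample size must exceed the total component count")
    params = init_params.copy() if init_params is not None else \
        initialize_params(x, y, z, dims, family="gaussian", seed=seed)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(max_iter + 1):
        moments = e_step_normal(params, x, y, z)
        trace.append(moments.loglik)
        if it > 0:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
            if not rel >= tol:  # also stops on nan
                converged = True
                break
        if it == max_iter:
            break
        a, b, sigma_g2 = m_step_outcome_normal(moments, z)
        block = m_step_po2pls_block(moments, params)
        params = ModelParams(family="gaussian", a0=0.0, a=a, b=b,
                             sigma_g2=sigma_g2, **block)
        n_iter = it + 1
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning the "
                      "last iterate", RuntimeWarning)
    params = canonicalize_signs(sort_components(params))
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=n_iter, converged=converged, tol_used=tol,
                     x_mean=xm, y_mean=ym, z_mean=zm)
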