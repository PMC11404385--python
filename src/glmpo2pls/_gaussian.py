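"""Low-rank multivariate-normal machinery shared by the EM routines.

The observed vector psi = (x, y[, z]) is a linear map of the base latent
vector zeta0 = (t, h, t_perp, u_perp) plus independent diagonal noise:

    psi = zeta0 @ L.T + noise,   zeta0 ~ N(0, diag(D)),  noise ~ N(0, diag(r))

so Sigma_psi = L diag(D) L' + diag(r).  All conditioning, log-likelihood and
determinant work is done through the d0 x d0 posterior precision
M = diag(1/D) + L' R^-1 L (Woodbury / Bayesian linear model identities),
never through a dense (p+q+1)^2 inverse.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

_LOG2PI = np.log(2.0 * np.pi)


def loading_factor(params, include_z: bool = True):
    """Assemble (L, D, r) for psi = (x, y[, z]) over zeta0 = (t, h, tp, up).

    For the bernoulli family the z row uses the linear predictor's loadings
    (a, b) and its "noise" is zero; callers for that family must pass
    ``include_z=False`` and handle the outcome by quadrature instead.
    """
    p, q = params.W.shape[0], params.C.shape[0]
    K, Kx, Ky = params.W.shape[1], params.Wperp.shape[1], params.Cperp.shape[1]
    d0 = 2 * K + Kx + Ky
    nrow = p + q + (1 if include_z else 0)
    L = np.zeros((nrow, d0))
    # x = t W' + tp Wperp' + e
    L[:p, :K] = params.W
    L[:p, 2 * K:2 * K + Kx] = params.Wperp
    # y = (tB + h) C' + up Cperp' + f
    L[p:p + q, :K] = params.C * params.B
    L[p:p + q, K:2 * K] = params.C
    L[p:p + q, 2 * K + Kx:] = params.Cperp
    D = np.concatenate([params.sigma_t, params.sigma_h,
                        params.sigma_tperp, params.sigma_uperp])
    r = np.concatenate([np.full(p, params.sigma_e2), np.full(q, params.sigma_f2)])
    if include_z:
        # z = t a' + h b' + g
        L[p + q, :K] = params.a
        L[p + q, K:2 * K] = params.b
        r = np.append(r, params.sigma_g2)
    return L, D, r


class LowRankNormal:
    """Zero-mean normal with covariance L diag(D) L' + diag(r)."""

    def __init__(self, L: np.ndarray, D: np.ndarray, r: np.ndarray):
        if np.any(D <= 0) or np.any(r <= 0):
            raise np.linalg.LinAlgError(
                "non-positive latent or noise variance: covariance is not PD")
        self.L, self.D, self.r = L, D, r
        self.dim = L.shape[0]
        self._Rinv_L = L / r[:, None]
        G = L.T @ self._Rinv_L
        M = np.diag(1.0 / D) + G
        try:
            self._cho = linalg.cho_factor(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - invalid inputs
            raise np.linalg.LinAlgError(f"posterior precision not PD: {exc}")
        self.logdet = (np.log(r).sum() + np.log(D).sum()
                       + 2.0 * np.log(np.diag(self._cho[0])).sum())
        self._cov = None

    @property
    def posterior_cov(self) -> np.ndarray:
        """Cov(zeta0 | psi); constant across observations."""
        if self._cov is None:
            self._cov = linalg.cho_solve(self._cho, np.eye(self.L.shape[1]))
            self._cov = 0.5 * (self._cov + self._cov.T)
        return self._cov

    def posterior_mean(self, psi: np.ndarray) -> np.ndarray:
        """E[zeta0 | psi] for each row of psi (N x d0)."""
        P = psi @ self._Rinv_L
        return linalg.cho_solve(self._cho, P.T).T

    def maha(self, psi: np.ndarray) -> np.ndarray:
        """Per-row Mahalanobis distances psi Sigma^-1 psi'."""
        P = psi @ self._Rinv_L
        sol = linalg.cho_solve(self._cho, P.T).T
        return ((psi ** 2) / self.r).sum(axis=1) - (P * sol).sum(axis=1)

    def posterior_mean_and_logpdf(self, psi: np.ndarray):
        """(E[zeta0 | psi_i], per-row log-density) in one pass."""
        P = psi @ self._Rinv_L
        sol = linalg.cho_solve(self._cho, P.T).T
        maha = ((psi ** 2) / self.r).sum(axis=1) - (P * sol).sum(axis=1)
        logpdf = -0.5 * (self.dim * _LOG2PI + self.logdet + maha)
        return sol, logpdf

    def loglik(self, psi: np.ndarray, sq_colsums: np.ndarray | None = None) -> float:
        """Sum over rows of the zero-mean normal log-density."""
        n = psi.shape[0]
        if sq_colsums is None:
            sq_colsums = (psi ** 2).sum(axis=0)
        P = psi @ self._Rinv_L
        sol = linalg.cho_solve(self._cho, P.T).T
        quad = (sq_colsums / self.r).sum() - (P * sol).sum()
        return -0.5 * (n * (self.dim * _LOG2PI + self.logdet) + quad)

    def solve(self, v: np.ndarray) -> np.ndarray:
        """Sigma^-1 @ v for v with leading dimension self.dim."""
        rv = v / self.r[:, None] if v.ndim == 2 else v / self.r
        corr = self._Rinv_L @ linalg.cho_solve(self._cho, self.L.T @ rv)
        return rv - corr

    def dense(self) -> np.ndarray:
        return (self.L * self.D) @ self.L.T + np.diag(self.r)
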