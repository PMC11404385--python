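"""Asymptotic inference for the omics-outcome association.

The covariance of alpha_hat = (a_hat, b_hat) is estimated from the observed
Fisher information via Louis' decomposition

    I(theta) = sum_i E[B_i | psi_i] - sum_i sum_j E[S_i S_j' | psi_i, psi_j]

restricted to the alpha block of the complete-data outcome term (alpha_hat is
treated as asymptotically independent from the remaining parameters and
sigma_g2 as non-random).  For independent subjects the double sum equals
sum_i E[S_i S_i'] + sum_{i != j} E[S_i] E[S_j]'; the cross term is ~0 at the
MLE but kept for fidelity.  The full test T = alpha Pi^-1 alpha' is referred
to chi-square with 2r df; each component-wise test (a_k, b_k) has 2 df.

For the bernoulli family the same construction is applied to the logistic
outcome term using quadrature moments; its p-values assume the asymptotic
normality carries over and are flagged with ``caveat=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from ._gaussian import LowRankNormal, loading_factor
from .em_binary import _PosteriorCore
from .em_normal import e_step_normal
from .results import FitResult

__all__ = ["InformationComponents", "InferenceResult", "alpha_information",
           "test_full", "test_componentwise", "test_omics_association",
           "test_association"]


@dataclass
class InformationComponents:
    """Observed-information pieces for the outcome-coefficient block."""

    info: np.ndarray            # information for (a, b) (gaussian) or (a0, a, b)
    Pi_alpha: np.ndarray        # 2r x 2r covariance of alpha_hat
    subject_scores: np.ndarray  # per-subject E[S_i | psi_i]
    family: str
    caveat: bool = False        # True when normality is assumed, not derived


@dataclass
class InferenceResult:
    alpha_hat: np.ndarray
    Pi_alpha: np.ndarray
    T_full: float
    df_full: int
    p_full: float
    T_comp: np.ndarray
    p_comp: np.ndarray
    df_comp: int = 2
    caveat: bool = False


def _gaussian_alpha_information(fit: FitResult, x, y, z) -> InformationComponents:
    params = fit.params
    K = params.dims.K
    moments = e_step_normal(params, x, y, z)
    # v = (t, h) moments: linear map of nu = (t, u)
    A = np.eye(2 * K)
    A[K:, :K] = -np.diag(params.B)
    mu = moments.nu_mean @ A.T                                   # N x 2K
    Gamma = A @ (moments.nu_second[0]
                 - np.outer(moments.nu_mean[0], moments.nu_mean[0])) @ A.T
    Gamma = 0.5 * (Gamma + Gamma.T)

    alpha = params.alpha
    s2 = params.sigma_g2
    n = mu.shape[0]
    e = np.asarray(z, float).reshape(-1) - mu @ alpha
    aG = Gamma @ alpha                                           # (2K,)
    aGa = float(alpha @ aG)
    emu = e[:, None] * mu
    sum_emu = emu.sum(axis=0)
    mu2 = mu.T @ mu

    term_B = (mu2 + n * Gamma) / s2
    A1 = (emu.T @ emu + float(e @ e) * Gamma
          - 2.0 * (np.outer(sum_emu, aG) + np.outer(aG, sum_emu))
          + aGa * mu2 + n * aGa * Gamma + 2.0 * np.outer(aG, aG))
    term_SS = A1 / s2 ** 2

    ES = (emu - aG[None, :]) / s2                                # E[S_i | psi_i]
    S_tot = ES.sum(axis=0)
    term_cross = np.outer(S_tot, S_tot) - ES.T @ ES

    info = term_B - term_SS - term_cross
    info = 0.5 * (info + info.T)
    try:
        Pi = linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular alpha information ({exc}); consider a smaller K") from exc
    return InformationComponents(info=info, Pi_alpha=0.5 * (Pi + Pi.T),
                                 subject_scores=ES, family="gaussian")


def _bernoulli_alpha_information(fit: FitResult, x, y, z,
                                 M: int = 16) -> InformationComponents:
    params = fit.params
    z = np.asarray(z, float).reshape(-1)
    core = _PosteriorCore(params, x, y, z, M)
    beta = np.concatenate([[params.a0], params.a, params.b])
    # per-(subject, node) design (1, t, h) and logistic mean
    d_full = core.d0[:, None, :] + core.dD[None, :, :]   # N x n_nodes x (1+2K)
    mu = 1.0 / (1.0 + np.exp(-(core.d0 @ beta)[:, None]
                             - (core.dD @ beta)[None, :]))
    omega = core.omega

    term_B = np.einsum("im,imp,imq->pq", omega * mu * (1.0 - mu),
                       d_full, d_full)
    resid = z[:, None] - mu
    term_SS = np.einsum("im,imp,imq->pq", omega * resid ** 2, d_full, d_full)
    ES = np.einsum("im,imp->ip", omega * resid, d_full)
    S_tot = ES.sum(axis=0)
    term_cross = np.outer(S_tot, S_tot) - ES.T @ ES

    info = term_B - term_SS - term_cross
    info = 0.5 * (info + info.T)
    try:
        Pi_full = linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular alpha information ({exc}); consider a smaller K") from exc
    return InformationComponents(info=info, Pi_alpha=Pi_full[1:, 1:],
                                 subject_scores=ES, family="bernoulli",
                                 caveat=True)


def alpha_information(fit: FitResult, x, y, z) -> InformationComponents:
    """Observed-information estimate of Cov(alpha_hat) at the fitted model.

    Data are centered with the training statistics stored in ``fit``.  Only
    the outcome term of the complete-data likelihood enters (the alpha-block
    shortcut); for the bernoulli family the intercept a0 is profiled through
    the full (a0, a, b) information and the result carries ``caveat=True``.
    """
    x = np.asarray(x, float) - fit.x_mean
    y = np.asarray(y, float) - fit.y_mean
    z = np.asarray(z, float).reshape(-1) - fit.z_mean
    if fit.params.family == "gaussian":
        return _gaussian_alpha_information(fit, x, y, z)
    return _bernoulli_alpha_information(fit, x, y, z)


def test_full(alpha_hat: np.ndarray, Pi_alpha: np.ndarray):
    """Full-association chi-square test of a = b = 0.

    Returns (T_full, df, p) with df = 2r.
    """
    alpha_hat = np.asarray(alpha_hat, float).reshape(-1)
    T = float(alpha_hat @ np.linalg.solve(Pi_alpha, alpha_hat))
    if T < 0:
        raise np.linalg.LinAlgError("Pi_alpha is not positive definite")
    df = alpha_hat.size
    return T, df, float(stats.chi2.sf(T, df))


def test_componentwise(alpha_hat: np.ndarray, Pi_alpha: np.ndarray, k: int):
    """Chi-square test of a_k = b_k = 0 for component k (1-based), df = 2."""
    alpha_hat = np.asarray(alpha_hat, float).reshape(-1)
    K = alpha_hat.size // 2
    if not 1 <= k <= K:
        raise ValueError(f"component index k={k} outside 1..{K}")
    idx = [k - 1, K + k - 1]
    sub = Pi_alpha[np.ix_(idx, idx)]
    a_k = alpha_hat[idx]
    T = float(a_k @ np.linalg.solve(sub, a_k))
    if T < 0:
        raise np.linalg.LinAlgError("Pi_alpha sub-block is not positive definite")
    return T, 2, float(stats.chi2.sf(T, 2))


def test_omics_association(fit: FitResult, x, y):
    """Per-component Wald tests of B_k = 0 (the t-u relationship).

    Uses the same Louis observed-information construction on the complete-data
    u | t term, with (t, u) moments conditioned on (x, y).  Returns arrays
    (B, T, p) of length K; each T is chi-square with 1 df under the null.
    """
    params = fit.params
    x = np.asarray(x, float) - fit.x_mean
    y = np.asarray(y, float) - fit.y_mean
    K = params.dims.K
    lr = LowRankNormal(*loading_factor(params, include_z=False))
    psi = np.hstack([x, y])
    mean0 = lr.posterior_mean(psi)      # zeta0 = (t, h, tp, up)
    cov0 = lr.posterior_cov
    n = psi.shape[0]

    B, sh = params.B, params.sigma_h
    T_stats = np.empty(K)
    p_vals = np.empty(K)
    for k in range(K):
        mt = mean0[:, k]
        mh = mean0[:, K + k]
        mu_u = mt * B[k] + mh
        g_tt = cov0[k, k]
        g_th = cov0[k, K + k]
        g_hh = cov0[K + k, K + k]
        g_tu = B[k] * g_tt + g_th
        g_uu = B[k] ** 2 * g_tt + 2 * B[k] * g_th + g_hh
        # eps = u - B t has mean m, var s, cov(eps, t) = c per subject
        m = mu_u - B[k] * mt
        s = g_uu - 2 * B[k] * g_tu + B[k] ** 2 * g_tt
        c = g_tu - B[k] * g_tt
        EB = ((mt ** 2 + g_tt) / sh[k]).sum()
        ES = (m * mt + c) / sh[k]
        ES2 = ((m ** 2 + s) * (mt ** 2 + g_tt)
               + 4 * m * mt * c + 2 * c ** 2) / sh[k] ** 2
        S_tot = ES.sum()
        info_k = EB - ES2.sum() - (S_tot ** 2 - (ES ** 2).sum())
        if info_k <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive information for B_{k + 1}; consider a smaller K")
        T_stats[k] = B[k] ** 2 * info_k
        p_vals[k] = stats.chi2.sf(T_stats[k], 1)
    return params.B.copy(), T_stats, p_vals


def test_association(fit: FitResult, x, y, z) -> InferenceResult:
    """Full and component-wise chi-square tests of the omics-outcome link."""
    comps = alpha_information(fit, x, y, z)
    alpha_hat = fit.params.alpha
    T, df, p = test_full(alpha_hat, comps.Pi_alpha)
    K = fit.params.dims.K
    T_comp = np.empty(K)
    p_comp = np.empty(K)
    for k in range(1, K + 1):
        T_comp[k - 1], _, p_comp[k - 1] = test_componentwise(
            alpha_hat, comps.Pi_alpha, k)
    return InferenceResult(alpha_hat=alpha_hat, Pi_alpha=comps.Pi_alpha,
                           T_full=T, df_full=df, p_full=p,
                           T_comp=T_comp, p_comp=p_comp, caveat=comps.caveat)
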