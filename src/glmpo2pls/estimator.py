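"""Scikit-learn style estimator for the two-omics + outcome model."""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._gaussian import LowRankNormal, loading_factor
from .em_binary import fit_binary
from .em_normal import fit_normal
from .inference import InferenceResult, test_association
from .params import ModelDims


class GLMPO2PLS(BaseEstimator):
    """Joint probabilistic model of two omics blocks and an outcome.

    Decomposes paired data matrices x (N x p) and y (N x q) into K joint,
    Kx/Ky block-specific and residual parts, and links the outcome z to the
    joint latent variables through an identity (gaussian z) or logit
    (bernoulli z) link.  Estimation is maximum likelihood by EM; the
    association between outcome and omics can be tested with asymptotic
    chi-square statistics.

    Parameters
    ----------
    n_joint, n_specific_x, n_specific_y : int
        Number of joint (K) and block-specific (Kx, Ky) latent components.
    family : {"gaussian", "bernoulli"}
        Outcome distribution.
    tol : float
        Relative log-likelihood change declaring EM convergence.
    max_iter : int
        EM iteration budget.
    n_quad : int
        Gauss-Hermite nodes per dimension (bernoulli family only).
    random_state : int or None
        Jitters the SVD-based initialization when set (random restarts).

    Attributes
    ----------
    params_ : ModelParams
        Canonicalized maximum-likelihood parameter collection.
    x_loadings_, y_loadings_ : ndarray
        Joint loading matrices W (p x K) and C (q x K).
    x_specific_loadings_, y_specific_loadings_ : ndarray
        Specific loading matrices.
    coef_a_, coef_b_ : ndarray
        Outcome coefficients for t (total x-effect) and h (direct y-effect).
    intercept_ : float
        a0 (0 for the gaussian family).
    loglik_trace_, n_iter_, converged_ : EM diagnostics.
    """

    def __init__(self, n_joint: int = 1, n_specific_x: int = 1,
                 n_specific_y: int = 1, family: str = "gaussian",
                 tol: float = 1e-6, max_iter: int = 10_000, n_quad: int = 16,
                 random_state=None):
        self.n_joint = n_joint
        self.n_specific_x = n_specific_x
        self.n_specific_y = n_specific_y
        self.family = family
        self.tol = tol
        self.max_iter = max_iter
        self.n_quad = n_quad
        self.random_state = random_state

    def _validate(self, x, y, z=None):
        x = check_array(x, dtype=np.float64)
        y = check_array(y, dtype=np.float64)
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y must have the same number of samples")
        if z is not None:
            z = np.asarray(z, float).reshape(-1)
            if z.shape[0] != x.shape[0]:
                raise ValueError("z length must match the number of samples")
        return x, y, z

    def fit(self, x, y, z):
        """Fit the model to omics blocks x, y and outcome z."""
        x, y, z = self._validate(x, y, z)
        dims = ModelDims(p=x.shape[1], q=y.shape[1], K=self.n_joint,
                         Kx=self.n_specific_x, Ky=self.n_specific_y,
                         N=x.shape[0])
        if self.family == "gaussian":
            fit = fit_normal(x, y, z, dims, tol=self.tol,
                             max_iter=self.max_iter, seed=self.random_state)
        elif self.family == "bernoulli":
            fit = fit_binary(x, y, z, dims, M=self.n_quad, tol=self.tol,
                             max_iter=self.max_iter, seed=self.random_state)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        self.fit_result_ = fit
        self.params_ = fit.params
        self.x_loadings_ = fit.params.W
        self.y_loadings_ = fit.params.C
        self.x_specific_loadings_ = fit.params.Wperp
        self.y_specific_loadings_ = fit.params.Cperp
        self.coef_a_ = fit.params.a
        self.coef_b_ = fit.params.b
        self.intercept_ = fit.params.a0
        self.loglik_trace_ = fit.loglik_trace
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.n_features_x_ = x.shape[1]
        self.n_features_y_ = y.shape[1]
        return self

    def _latent_means(self, x, y):
        fit = self.fit_result_
        x = check_array(x, dtype=np.float64) - fit.x_mean
        y = check_array(y, dtype=np.float64) - fit.y_mean
        lr = LowRankNormal(*loading_factor(self.params_, include_z=False))
        return lr.posterior_mean(np.hstack([x, y]))

    def transform(self, x, y):
        """Posterior means of the joint scores (t, u) given (x, y)."""
        check_is_fitted(self, "params_")
        K = self.params_.dims.K
        m = self._latent_means(x, y)
        t = m[:, :K]
        u = t * self.params_.B + m[:, K:2 * K]
        return t, u

    def decision_function(self, x, y):
        """Linear predictor a0 + E[t]a' + E[h]b' given (x, y)."""
        check_is_fitted(self, "params_")
        K = self.params_.dims.K
        m = self._latent_means(x, y)
        return (self.params_.a0 + m[:, :K] @ self.coef_a_
                + m[:, K:2 * K] @ self.coef_b_)

    def predict(self, x, y):
        """E[z | x, y]: conditional mean (gaussian) or probability (bernoulli)."""
        eta = self.decision_function(x, y)
        if self.family == "gaussian":
            return eta + self.fit_result_.z_mean
        return expit(eta)

    def score(self, x, y, z) -> float:
        """Average observed-data log-likelihood per sample."""
        check_is_fitted(self, "params_")
        from .em_binary import loglik_binary
        from .em_normal import loglik_normal
        fit = self.fit_result_
        x, y, z = self._validate(x, y, z)
        xc, yc = x - fit.x_mean, y - fit.y_mean
        if self.family == "gaussian":
            return loglik_normal(self.params_, xc, yc, z - fit.z_mean) / len(z)
        return loglik_binary(self.params_, xc, yc, z) / len(z)

    def test_association(self, x, y, z) -> InferenceResult:
        """Chi-square tests of the omics-outcome association (full + per component)."""
        check_is_fitted(self, "params_")
        x, y, z = self._validate(x, y, z)
        return test_association(self.fit_result_, x, y, z)
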