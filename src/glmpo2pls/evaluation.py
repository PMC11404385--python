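"""Simulation-study harness: metrics, ridge baselines, size/power drivers.

The drivers reproduce the published protocol: type-I error draws the outcome
standard normal independently of the simulated (x, y) and counts rejections
of the full test at the 5% level; power generates z under the model with
a = 2, b = 1.  Feature selection is scored as the true-positive rate of the
top 25% of x-features by absolute joint loading.  Rep counts are configurable
(the study used 500 replications for estimation metrics and 10,000 for type-I
error; desk-scale defaults are smaller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.special import expit, logit
from sklearn.linear_model import Ridge, RidgeCV

from ._gaussian import LowRankNormal, loading_factor
from .em_normal import fit_normal
from .inference import test_association
from .params import ModelDims, ModelParams
from .results import FitResult
from .simulate import (SimScenario, simulate_dataset, simulate_from_params,
                       simulate_null_outcome)

_EPS_PROB = 1e-12


def rmsep(pred, truth, family: str = "gaussian") -> float:
    """Root mean square error of prediction.

    For the bernoulli family both arguments are probabilities and the error
    is measured on the logit scale; probabilities at 0/1 are clipped to
    [1e-12, 1 - 1e-12] with a warning.
    """
    pred = np.asarray(pred, float).reshape(-1)
    truth = np.asarray(truth, float).reshape(-1)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if family == "bernoulli":
        if ((pred <= 0) | (pred >= 1) | (truth <= 0) | (truth >= 1)).any():
            warnings.warn("probabilities at 0/1 clipped before logit",
                          RuntimeWarning)
        pred = logit(np.clip(pred, _EPS_PROB, 1 - _EPS_PROB))
        truth = logit(np.clip(truth, _EPS_PROB, 1 - _EPS_PROB))
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass
class BinaryPrediction:
    prob: np.ndarray
    logit: np.ndarray


def predict_outcome(fit: FitResult, x_new, y_new):
    """E[z | x, y] under a fitted model, on new data.

    New data are centered by the training statistics.  Gaussian family:
    returns the conditional mean.  Bernoulli: returns a ``BinaryPrediction``
    with the plug-in probability and the logit-scale linear predictor.
    """
    params = fit.params
    x = np.asarray(x_new, float)
    y = np.asarray(y_new, float)
    if x.shape[1] != params.dims.p or y.shape[1] != params.dims.q:
        raise ValueError("new data dimensions do not match the fitted model")
    x = x - fit.x_mean
    y = y - fit.y_mean
    K = params.dims.K
    lr = LowRankNormal(*loading_factor(params, include_z=False))
    m = lr.posterior_mean(np.hstack([x, y]))
    eta = params.a0 + m[:, :K] @ params.a + m[:, K:2 * K] @ params.b
    if params.family == "gaussian":
        return eta + fit.z_mean
    return BinaryPrediction(prob=expit(eta), logit=eta)


def tpr_top_quantile(loadings_est, loadings_true, fraction: float = 0.25) -> float:
    """TP/(TP+FN) for recovering the top-|loading| fraction of features.

    Ties at the cutoff are broken by feature index (stable sort).
    """
    est = np.abs(np.asarray(loadings_est, float).reshape(-1))
    true = np.abs(np.asarray(loadings_true, float).reshape(-1))
    if est.shape != true.shape:
        raise ValueError("loading vectors must have equal length")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    m = int(np.ceil(fraction * est.size))
    top_est = set(np.argsort(-est, kind="stable")[:m])
    top_true = set(np.argsort(-true, kind="stable")[:m])
    return len(top_est & top_true) / m


@dataclass
class RidgeFit:
    coef: np.ndarray
    alpha: float
    x_mean: np.ndarray
    z_mean: float

    def predict(self, x_new) -> np.ndarray:
        return (np.asarray(x_new, float) - self.x_mean) @ self.coef + self.z_mean


def ridge_baseline(x, z, folds: int = 10, alphas=None,
                   alpha: float | None = None) -> RidgeFit:
    """Ridge regression of z on one block; penalty by k-fold CV unless fixed.

    With ``alpha`` given, fits that fixed penalty (matching the closed form
    (X'X + alpha I)^-1 X'z on centered data).
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float).reshape(-1)
    xm, zm = x.mean(axis=0), float(z.mean())
    xc, zc = x - xm, z - zm
    if alpha is not None:
        model = Ridge(alpha=alpha, fit_intercept=False, solver="svd")
    else:
        if alphas is None:
            alphas = np.logspace(-3, 5, 25)
        model = RidgeCV(alphas=alphas, fit_intercept=False, cv=folds)
    model.fit(xc, zc)
    used = alpha if alpha is not None else float(model.alpha_)
    return RidgeFit(coef=model.coef_.copy(), alpha=used, x_mean=xm, z_mean=zm)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit child seeds from one master seed."""
    return (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)).astype(np.int64)


@dataclass
class RejectionSummary:
    rate: float
    se: float
    n_reject: int
    n_ok: int
    n_failed: int
    level: float


def _fit_and_test(x, y, z, scenario: SimScenario, fit_kwargs) -> bool:
    dims = ModelDims(p=scenario.p, q=scenario.q, K=scenario.K,
                     Kx=scenario.Kx, Ky=scenario.Ky)
    fit = fit_normal(x, y, z, dims, **fit_kwargs)
    return test_association(fit, x, y, z)


def run_type1_experiment(scenario: SimScenario, reps: int, level: float = 0.05,
                         seed: int = 0, fit_kwargs: dict | None = None,
                         n_jobs: int = 1) -> RejectionSummary:
    """Empirical size of the full test under the independent-outcome null."""
    fit_kwargs = fit_kwargs or {}
    seeds = _spawn_seeds(seed, 2 * reps)

    def one(i):
        sc = scenario.with_(seed=int(seeds[2 * i]))
        x, y, _, _, _ = simulate_dataset(sc)
        z = simulate_null_outcome(x, y, int(seeds[2 * i + 1]))
        try:
            res = _fit_and_test(x, y, z, sc, fit_kwargs)
            return bool(res.p_full < level)
        except np.linalg.LinAlgError:
            return None

    flags = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(reps))
    ok = [f for f in flags if f is not None]
    n_rej = sum(ok)
    rate = n_rej / len(ok) if ok else float("nan")
    se = float(np.sqrt(rate * (1 - rate) / len(ok))) if ok else float("nan")
    return RejectionSummary(rate=rate, se=se, n_reject=n_rej, n_ok=len(ok),
                            n_failed=reps - len(ok), level=level)


def run_power_experiment(scenario: SimScenario, reps: int, level: float = 0.05,
                         seed: int = 0, fit_kwargs: dict | None = None,
                         n_jobs: int = 1) -> RejectionSummary:
    """Empirical power of the full test under the model alternative."""
    fit_kwargs = fit_kwargs or {}
    seeds = _spawn_seeds(seed, reps)

    def one(i):
        sc = scenario.with_(seed=int(seeds[i]))
        x, y, z, _, _ = simulate_dataset(sc)
        try:
            res = _fit_and_test(x, y, z, sc, fit_kwargs)
            return bool(res.p_full < level)
        except np.linalg.LinAlgError:
            return None

    flags = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(reps))
    ok = [f for f in flags if f is not None]
    n_rej = sum(ok)
    rate = n_rej / len(ok) if ok else float("nan")
    se = float(np.sqrt(rate * (1 - rate) / len(ok))) if ok else float("nan")
    return RejectionSummary(rate=rate, se=se, n_reject=n_rej, n_ok=len(ok),
                            n_failed=reps - len(ok), level=level)


def _align_to_truth(est: ModelParams, true: ModelParams) -> ModelParams:
    """Flip estimated component signs to the truth's orientation.

    Undoes the sign indeterminacy so scaled coefficient errors and loading
    inner products are comparable to the ground truth.
    """
    out = est.copy()
    for k in range(out.W.shape[1]):
        if out.W[:, k] @ true.W[:, k] < 0:   # flip t_k
            out.W[:, k] *= -1
            out.a[k] *= -1
            out.B[k] *= -1
        if out.C[:, k] @ true.C[:, k] < 0:   # flip u_k
            out.C[:, k] *= -1
            out.b[k] *= -1
            out.B[k] *= -1
    for name in ("Wperp", "Cperp"):
        E, T = getattr(out, name), getattr(true, name)
        for k in range(E.shape[1]):
            if E[:, k] @ T[:, k] < 0:
                E[:, k] *= -1
    return out


@dataclass
class MetricsRecord:
    scenario: str
    rep: int
    scaled_error_a: float
    scaled_error_b: float
    rmsep: float
    rmsep_ridge_x: float
    rmsep_ridge_y: float
    tpr_top25: float
    ip_W: float
    ip_Wperp: float
    ip_C: float
    ip_Cperp: float
    converged: bool


def evaluate_one_rep(scenario: SimScenario, rep_seed: int,
                     fit_kwargs: dict | None = None, test_n: int = 0,
                     with_ridge: bool = False, rep: int = 0,
                     label: str | None = None) -> MetricsRecord:
    """Simulate one dataset, fit, and score the Table-2 style metrics.

    ``test_n`` > 0 evaluates RMSEP on an independent test set of that size;
    ``with_ridge`` adds the per-block ridge comparators (CV penalty).
    """
    fit_kwargs = fit_kwargs or {}
    sc = scenario.with_(seed=int(rep_seed))
    x, y, z, _, truth = simulate_dataset(sc)
    dims = ModelDims(p=sc.p, q=sc.q, K=sc.K, Kx=sc.Kx, Ky=sc.Ky)
    if sc.family == "gaussian":
        fit = fit_normal(x, y, z, dims, **fit_kwargs)
    else:
        from .em_binary import fit_binary
        fit = fit_binary(x, y, z, dims, **fit_kwargs)
    est = _align_to_truth(fit.params, truth)

    rm = rm_x = rm_y = float("nan")
    if test_n > 0:
        # fresh draws from the same ground truth as the training data
        xt, yt, zt, lat_t = simulate_from_params(truth, test_n,
                                                 int(rep_seed) + 1)
        if sc.family == "gaussian":
            rm = rmsep(predict_outcome(fit, xt, yt), zt)
        else:
            p_true = expit(truth.a0 + lat_t.t @ truth.a + lat_t.h @ truth.b)
            rm = rmsep(predict_outcome(fit, xt, yt).prob, p_true,
                       family="bernoulli")
        if with_ridge:
            rfx = ridge_baseline(x, z)
            rfy = ridge_baseline(y, z)
            if sc.family == "gaussian":
                rm_x = rmsep(rfx.predict(xt), zt)
                rm_y = rmsep(rfy.predict(yt), zt)
            else:
                rm_x = rmsep(np.clip(rfx.predict(xt), _EPS_PROB, 1 - _EPS_PROB),
                             p_true, family="bernoulli")
                rm_y = rmsep(np.clip(rfy.predict(yt), _EPS_PROB, 1 - _EPS_PROB),
                             p_true, family="bernoulli")

    return MetricsRecord(
        scenario=label or f"N{sc.N}_p{sc.p}_q{sc.q}",
        rep=rep,
        scaled_error_a=float((est.a[0] - truth.a[0]) / truth.a[0]),
        scaled_error_b=float((est.b[0] - truth.b[0]) / truth.b[0]),
        rmsep=rm, rmsep_ridge_x=rm_x, rmsep_ridge_y=rm_y,
        tpr_top25=tpr_top_quantile(est.W[:, 0], truth.W[:, 0]),
        ip_W=float(est.W[:, 0] @ truth.W[:, 0]),
        ip_Wperp=float(est.Wperp[:, 0] @ truth.Wperp[:, 0]),
        ip_C=float(est.C[:, 0] @ truth.C[:, 0]),
        ip_Cperp=float(est.Cperp[:, 0] @ truth.Cperp[:, 0]),
        converged=fit.converged,
    )


def run_scenario_grid(scenarios, reps: int, seed: int = 0,
                      fit_kwargs: dict | None = None, test_n: int = 0,
                      with_ridge: bool = False, n_jobs: int = 1) -> pd.DataFrame:
    """Metrics over a grid of scenarios, long format (one row per rep)."""
    if isinstance(scenarios, SimScenario):
        scenarios = [scenarios]
    rows = []
    for si, sc in enumerate(scenarios):
        seeds = _spawn_seeds(seed + si, reps)
        recs = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_one_rep)(sc, int(seeds[r]), fit_kwargs,
                                      test_n, with_ridge, rep=r)
            for r in range(reps))
        rows.extend(recs)
    return pd.DataFrame([r.__dict__ for r in rows])
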