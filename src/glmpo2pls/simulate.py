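"""Model-faithful data generator for the simulation-study scenario grid.

Defaults reproduce the published study design: sample sizes 100/1000, block
dimensions (p, q) = (100, 10) or (2000, 25), one joint and one specific
component per block, latents standard normal, B = I, heterogeneity (the
variance share of h in u) 40% or 80%, residual variance fractions 40%/40%
(low noise) or 95%/5% (high noise in x, low in y), outcome noise 20% of
var(z), and true coefficients a = 2, b = 1.

"Noise proportion" is read as the trace ratio: expected residual variance
over expected total variance summed over features of a block.  One master
seed is expanded into independent substreams (loadings, latents, noise,
outcome) so every scenario is reproducible component-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import LatentState, ModelParams

__all__ = ["SimScenario", "make_loadings", "calibrate_variances",
           "simulate_dataset", "simulate_null_outcome"]


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation grid; defaults are the benign low-dim cell."""

    N: int = 100
    p: int = 100
    q: int = 10
    K: int = 1
    Kx: int = 1
    Ky: int = 1
    heterogeneity: float = 0.4   # var(h) / var(u)
    noise_x: float = 0.4         # residual variance fraction in x
    noise_y: float = 0.4
    noise_z: float = 0.2         # residual fraction of var(z), gaussian only
    a_coef: float = 2.0
    b_coef: float = 1.0
    family: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        for name in ("heterogeneity", "noise_x", "noise_y", "noise_z"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def with_(self, **kw) -> "SimScenario":
        return replace(self, **kw)


def make_loadings(dim: int, ncomp: int, seed) -> np.ndarray:
    """Standard-normal matrix with columns then orthonormalized (QR).

    ``seed`` may be an int or a numpy Generator/SeedSequence.
    """
    if ncomp > dim:
        raise ValueError(f"ncomp={ncomp} exceeds dim={dim}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((dim, ncomp))
    Q, R = np.linalg.qr(A)
    # fix QR's sign convention so the map seed -> loadings is well defined
    return Q * np.sign(np.diag(R))


def calibrate_variances(scenario: SimScenario, loadings: dict) -> ModelParams:
    """Solve the residual variances so the stated variance fractions hold.

    Latents follow the standard-normal convention (Sigma_t = Sigma_tperp =
    Sigma_uperp = I for K = 1; for K >= 2 Sigma_t is the decreasing sequence
    K..1 so diag(Sigma_t B) is strictly decreasing), B = I, and Sigma_h is
    set from the heterogeneity fraction: var(h)/var(u) = f gives
    Sigma_h = f/(1-f) * B^2 Sigma_t.
    """
    sc = scenario
    K, Kx, Ky = sc.K, sc.Kx, sc.Ky
    sigma_t = np.arange(K, 0, -1, dtype=float) if K > 1 else np.ones(1)
    B = np.ones(K)
    f = sc.heterogeneity
    sigma_h = f / (1.0 - f) * B ** 2 * sigma_t
    sigma_tperp = np.ones(Kx)
    sigma_uperp = np.ones(Ky)
    sigma_u = B ** 2 * sigma_t + sigma_h

    # trace-ratio calibration: sigma2 * dim / trace(Sigma_block) = fraction
    signal_x = sigma_t.sum() + sigma_tperp.sum()
    signal_y = sigma_u.sum() + sigma_uperp.sum()
    sigma_e2 = sc.noise_x * signal_x / (sc.p * (1.0 - sc.noise_x))
    sigma_f2 = sc.noise_y * signal_y / (sc.q * (1.0 - sc.noise_y))

    a = np.full(K, sc.a_coef)
    b = np.full(K, sc.b_coef)
    var_eta = float(a @ (sigma_t * a) + b @ (sigma_h * b))
    sigma_g2 = sc.noise_z / (1.0 - sc.noise_z) * var_eta

    return ModelParams(
        W=loadings["W"], C=loadings["C"],
        Wperp=loadings["Wperp"], Cperp=loadings["Cperp"],
        B=B, sigma_t=sigma_t, sigma_tperp=sigma_tperp, sigma_uperp=sigma_uperp,
        sigma_h=sigma_h, sigma_e2=sigma_e2, sigma_f2=sigma_f2,
        family=sc.family, a0=0.0, a=a, b=b,
        sigma_g2=sigma_g2 if sc.family == "gaussian" else None,
    )


def _loadings_from_streams(sc: SimScenario, seeds) -> dict:
    names = ("W", "Wperp", "C", "Cperp")
    dims = ((sc.p, sc.K), (sc.p, sc.Kx), (sc.q, sc.K), (sc.q, sc.Ky))
    return {n: make_loadings(d, k, s) for n, (d, k), s in zip(names, dims, seeds)}


def true_params(scenario: SimScenario) -> ModelParams:
    """Ground-truth parameters for a scenario (deterministic given its seed)."""
    ss = np.random.SeedSequence(scenario.seed)
    loadings = _loadings_from_streams(scenario, ss.spawn(6)[:4])
    return calibrate_variances(scenario, loadings)


def simulate_dataset(scenario: SimScenario):
    """Draw (x, y, z) plus latent ground truth under the generative model.

    Returns ``(x, y, z, latents, params)`` where z is continuous or 0/1
    according to the scenario family.  Deterministic given ``scenario.seed``;
    loadings, latents, noise and outcome use independent substreams.
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    s_load = ss.spawn(6)
    loadings = _loadings_from_streams(sc, s_load[:4])
    params = calibrate_variances(sc, loadings)
    rng_lat = np.random.default_rng(s_load[4])
    rng_noise = np.random.default_rng(s_load[5])

    N = sc.N
    t = rng_lat.standard_normal((N, sc.K)) * np.sqrt(params.sigma_t)
    h = rng_lat.standard_normal((N, sc.K)) * np.sqrt(params.sigma_h)
    tperp = rng_lat.standard_normal((N, sc.Kx)) * np.sqrt(params.sigma_tperp)
    uperp = rng_lat.standard_normal((N, sc.Ky)) * np.sqrt(params.sigma_uperp)
    u = t * params.B + h

    e = rng_noise.standard_normal((N, sc.p)) * np.sqrt(params.sigma_e2)
    f = rng_noise.standard_normal((N, sc.q)) * np.sqrt(params.sigma_f2)
    x = t @ params.W.T + tperp @ params.Wperp.T + e
    y = u @ params.C.T + uperp @ params.Cperp.T + f

    eta = params.a0 + t @ params.a + h @ params.b
    if sc.family == "gaussian":
        g = rng_noise.standard_normal(N) * np.sqrt(params.sigma_g2)
        z = eta + g
    else:
        prob = 1.0 / (1.0 + np.exp(-eta))
        z = (rng_noise.random(N) < prob).astype(float)
        g = None
    latents = LatentState(t=t, u=u, tperp=tperp, uperp=uperp, h=h, e=e, f=f, g=g)
    return x, y, z, latents, params


def simulate_from_params(params: ModelParams, N: int, seed):
    """Draw (x, y, z, latents) from an explicit parameter collection.

    Used e.g. for independent test sets that share the training ground truth.
    """
    rng = np.random.default_rng(seed)
    d = params.dims
    t = rng.standard_normal((N, d.K)) * np.sqrt(params.sigma_t)
    h = rng.standard_normal((N, d.K)) * np.sqrt(params.sigma_h)
    tperp = rng.standard_normal((N, d.Kx)) * np.sqrt(params.sigma_tperp)
    uperp = rng.standard_normal((N, d.Ky)) * np.sqrt(params.sigma_uperp)
    u = t * params.B + h
    e = rng.standard_normal((N, d.p)) * np.sqrt(params.sigma_e2)
    f = rng.standard_normal((N, d.q)) * np.sqrt(params.sigma_f2)
    x = t @ params.W.T + tperp @ params.Wperp.T + e
    y = u @ params.C.T + uperp @ params.Cperp.T + f
    eta = params.a0 + t @ params.a + h @ params.b
    if params.family == "gaussian":
        g = rng.standard_normal(N) * np.sqrt(params.sigma_g2)
        z = eta + g
    else:
        z = (rng.random(N) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        g = None
    latents = LatentState(t=t, u=u, tperp=tperp, uperp=uperp, h=h, e=e, f=f, g=g)
    return x, y, z, latents


def simulate_null_outcome(x, y, seed) -> np.ndarray:
    """Standard-normal outcome independent of (x, y) (null protocol)."""
    n = np.asarray(x).shape[0]
    if np.asarray(y).shape[0] != n:
        raise ValueError("x and y must have the same number of rows")
    return np.random.default_rng(seed).standard_normal(n)
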