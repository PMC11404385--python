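import numpy as np
import pytest

from glmpo2pls.params import LatentState


def draw_from_params(params, N, rng):
    """Sample (x, y, z, latents) from an explicit parameter collection."""
    d = params.dims
    t = rng.standard_normal((N, d.K)) * np.sqrt(params.sigma_t)
    h = rng.standard_normal((N, d.K)) * np.sqrt(params.sigma_h)
    tp = rng.standard_normal((N, d.Kx)) * np.sqrt(params.sigma_tperp)
    up = rng.standard_normal((N, d.Ky)) * np.sqrt(params.sigma_uperp)
    u = t * params.B + h
    e = rng.standard_normal((N, d.p)) * np.sqrt(params.sigma_e2)
    f = rng.standard_normal((N, d.q)) * np.sqrt(params.sigma_f2)
    x = t @ params.W.T + tp @ params.Wperp.T + e
    y = u @ params.C.T + up @ params.Cperp.T + f
    eta = params.a0 + t @ params.a + h @ params.b
    if params.family == "gaussian":
        z = eta + rng.standard_normal(N) * np.sqrt(params.sigma_g2)
        g = z - eta
    else:
        z = (rng.random(N) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        g = None
    lat = LatentState(t=t, u=u, tperp=tp, uperp=up, h=h, e=e, f=f, g=g)
    return x, y, z, lat


def align_signs(est, truth):
    """Flip estimated component signs to the truth's orientation."""
    from glmpo2pls.evaluation import _align_to_truth
    return _align_to_truth(est, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_k2_params():
    """Valid K=2 parameters on a small (p=12, q=6) problem."""
    from glmpo2pls.simulate import SimScenario, simulate_dataset
    sc = SimScenario(N=10, p=12, q=6, K=2, Kx=2, Ky=1, seed=21)
    *_, params = simulate_dataset(sc)
    return params


@pytest.fixture(scope="session")
def small_gaussian():
    """Simulated gaussian-outcome dataset on a small problem."""
    from glmpo2pls.simulate import SimScenario, simulate_dataset
    sc = SimScenario(N=200, p=15, q=6, seed=7)
    x, y, z, lat, truth = simulate_dataset(sc)
    return x, y, z, lat, truth, sc
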