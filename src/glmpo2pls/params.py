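"""Model parameterization for the two-omics + outcome latent-variable model.

The generative model per subject (row vectors) is

    x = t W' + t_perp Wperp' + e,          e ~ N(0, sigma_e2 I_p)
    y = u C' + u_perp Cperp' + f,          f ~ N(0, sigma_f2 I_q)
    u = t B + h,                           h ~ N(0, Sigma_h)
    eta(E[z]) = a0 + t a' + h b'

with t, t_perp, u_perp zero-mean normal with diagonal covariances.  The
outcome coefficients are stored in the "total/direct effect" form: ``a``
multiplies t (the total x-effect) and ``b`` multiplies h = u - tB (the direct
y-effect).  For a gaussian outcome z = t a' + h b' + g with g ~ N(0, sigma_g2)
and a0 fixed at 0 (z is centered); for a bernoulli outcome the logit of
P(z=1) equals the linear predictor and a0 is a free intercept.

Identifiability (up to component-wise sign flips) requires semi-orthogonal
loading blocks, positive diagonal B and strictly decreasing diag(Sigma_t B).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._gaussian import loading_factor

FAMILIES = ("gaussian", "bernoulli")


@dataclass(frozen=True)
class ModelDims:
    """Problem dimensions; r (length of a, b) is fixed equal to K."""

    p: int
    q: int
    K: int
    Kx: int
    Ky: int
    N: int | None = None

    @property
    def r(self) -> int:
        return self.K

    def __post_init__(self):
        for name in ("p", "q", "K", "Kx", "Ky"):
            if getattr(self, name) < 1:
                raise ValueError(f"dimension {name} must be a positive integer")
        if self.K > min(self.p, self.q):
            raise ValueError("K must not exceed min(p, q)")
        if self.Kx >= self.p or self.Ky >= self.q:
            raise ValueError("specific component counts must be < p resp. q")


@dataclass
class ModelParams:
    """Full parameter collection; diagonal matrices stored as 1-D arrays."""

    W: np.ndarray          # p x K joint x-loadings, semi-orthogonal
    C: np.ndarray          # q x K joint y-loadings, semi-orthogonal
    Wperp: np.ndarray      # p x Kx specific x-loadings
    Cperp: np.ndarray      # q x Ky specific y-loadings
    B: np.ndarray          # K, positive diagonal of the t->u regression
    sigma_t: np.ndarray    # K, Var(t)
    sigma_tperp: np.ndarray
    sigma_uperp: np.ndarray
    sigma_h: np.ndarray    # K, Var(h)
    sigma_e2: float
    sigma_f2: float
    family: str = "gaussian"
    a0: float = 0.0
    a: np.ndarray | None = None   # 1 x K stored as (K,): total x-effect on z
    b: np.ndarray | None = None   # direct y-effect on z
    sigma_g2: float | None = None  # gaussian family only

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        for name in ("W", "C", "Wperp", "Cperp", "B", "sigma_t", "sigma_tperp",
                     "sigma_uperp", "sigma_h"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        K = self.W.shape[1]
        if self.a is None:
            self.a = np.zeros(K)
        if self.b is None:
            self.b = np.zeros(K)
        self.a = np.asarray(self.a, float).reshape(-1)
        self.b = np.asarray(self.b, float).reshape(-1)
        d = self.dims
        shapes = {
            "C": (d.q, d.K), "Wperp": (d.p, d.Kx), "Cperp": (d.q, d.Ky),
            "B": (d.K,), "sigma_t": (d.K,), "sigma_h": (d.K,),
            "sigma_tperp": (d.Kx,), "sigma_uperp": (d.Ky,),
            "a": (d.K,), "b": (d.K,),
        }
        for name, shape in shapes.items():
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        if self.family == "gaussian" and self.sigma_g2 is None:
            raise ValueError("sigma_g2 is required for the gaussian family")

    @property
    def dims(self) -> ModelDims:
        return ModelDims(p=self.W.shape[0], q=self.C.shape[0], K=self.W.shape[1],
                         Kx=self.Wperp.shape[1], Ky=self.Cperp.shape[1])

    @property
    def sigma_u(self) -> np.ndarray:
        """Var(u) = B Sigma_t B + Sigma_h (diagonals)."""
        return self.B ** 2 * self.sigma_t + self.sigma_h

    @property
    def alpha(self) -> np.ndarray:
        """Concatenated outcome coefficients (a, b), length 2K."""
        return np.concatenate([self.a, self.b])

    def copy(self) -> "ModelParams":
        return ModelParams(**{
            f.name: (v.copy() if isinstance(v := getattr(self, f.name), np.ndarray)
                     else v)
            for f in dataclasses.fields(self)})


@dataclass
class LatentState:
    """Ground-truth latent draws accompanying a simulated dataset."""

    t: np.ndarray
    u: np.ndarray
    tperp: np.ndarray
    uperp: np.ndarray
    h: np.ndarray
    e: np.ndarray
    f: np.ndarray
    g: np.ndarray | None = None

    @property
    def nu(self) -> np.ndarray:
        return np.hstack([self.t, self.u])

    @property
    def xi(self) -> np.ndarray:
        return np.hstack([self.tperp, self.uperp])


class JointCovariance:
    """Implied covariance of (x, y, z); blocks are built lazily and low-rank.

    For the bernoulli family the z row/column describes the covariance
    structure of the linear predictor (excluding any residual variance).
    """

    def __init__(self, params: ModelParams):
        self.params = params
        p = params.dims

        self.Sigma_u = np.diag(params.sigma_u)
        st_b = params.sigma_t * params.B
        self.Sigma_nu = np.block([
            [np.diag(params.sigma_t), np.diag(st_b)],
            [np.diag(st_b), self.Sigma_u],
        ])
        self.var_z = float(params.a @ (params.sigma_t * params.a)
                           + params.b @ (params.sigma_h * params.b))
        if params.family == "gaussian":
            self.var_z += params.sigma_g2
        self.cov_xz = params.W @ (params.sigma_t * params.a)
        self.cov_yz = params.C @ (params.sigma_h * params.b + st_b * params.a)
        self._p, self._q = p.p, p.q

    @property
    def Sigma_x_given_t(self) -> np.ndarray:
        pr = self.params
        return ((pr.Wperp * pr.sigma_tperp) @ pr.Wperp.T
                + pr.sigma_e2 * np.eye(self._p))

    @property
    def Sigma_y_given_u(self) -> np.ndarray:
        pr = self.params
        return ((pr.Cperp * pr.sigma_uperp) @ pr.Cperp.T
                + pr.sigma_f2 * np.eye(self._q))

    @property
    def Sigma_xx(self) -> np.ndarray:
        pr = self.params
        return (pr.W * pr.sigma_t) @ pr.W.T + self.Sigma_x_given_t

    @property
    def Sigma_yy(self) -> np.ndarray:
        pr = self.params
        return (pr.C * np.diag(self.Sigma_u)) @ pr.C.T + self.Sigma_y_given_u

    @property
    def Sigma_xy(self) -> np.ndarray:
        pr = self.params
        return (pr.W * (pr.sigma_t * pr.B)) @ pr.C.T

    @property
    def Sigma_theta(self) -> np.ndarray:
        """Dense (p+q+1) x (p+q+1) covariance of (x, y, z)."""
        p, q = self._p, self._q
        S = np.empty((p + q + 1, p + q + 1))
        S[:p, :p] = self.Sigma_xx
        S[:p, p:p + q] = self.Sigma_xy
        S[p:p + q, :p] = S[:p, p:p + q].T
        S[p:p + q, p:p + q] = self.Sigma_yy
        S[:p, -1] = self.cov_xz
        S[-1, :p] = self.cov_xz
        S[p:p + q, -1] = self.cov_yz
        S[-1, p:p + q] = self.cov_yz
        S[-1, -1] = self.var_z
        return S


def validate_params(params: ModelParams, tol: float = 1e-8) -> list[str]:
    """Check the identifiability invariants; return a list of violations.

    An empty list means every constraint holds within ``tol``.  Dimension
    inconsistencies raise (they are structural errors, not violations).
    """
    report: list[str] = []
    for name, M in (("W", params.W), ("C", params.C),
                    ("Wperp", params.Wperp), ("Cperp", params.Cperp)):
        dev = np.abs(M.T @ M - np.eye(M.shape[1])).max()
        if dev > tol:
            report.append(f"{name} not semi-orthogonal (max deviation {dev:.3e})")
    for name, M, Mp in (("[W Wperp]", params.W, params.Wperp),
                        ("[C Cperp]", params.C, params.Cperp)):
        joint = np.hstack([M, Mp])
        rank = np.linalg.matrix_rank(joint, tol=max(tol, 1e-10) * joint.shape[0])
        if rank < joint.shape[1]:
            report.append(f"{name} is column-rank deficient (rank {rank})")
    if np.any(params.B <= 0):
        report.append(f"B positivity violated (min diag {params.B.min():.3e})")
    stb = params.sigma_t * params.B
    if np.any(np.diff(stb) >= 0):
        report.append("diag(Sigma_t B) not strictly decreasing")
    for name in ("sigma_t", "sigma_tperp", "sigma_uperp", "sigma_h"):
        v = getattr(params, name)
        if np.any(v <= 0):
            report.append(f"{name} has non-positive entries (min {v.min():.3e})")
    for name in ("sigma_e2", "sigma_f2") + (
            ("sigma_g2",) if params.family == "gaussian" else ()):
        v = getattr(params, name)
        if v is None or v <= 0:
            report.append(f"{name} must be positive (got {v})")
    return report


def build_joint_covariance(params: ModelParams) -> JointCovariance:
    """Covariance blocks of (x, y, z) implied by the parameters."""
    return JointCovariance(params)


def reparameterize(a_raw: np.ndarray, b_raw: np.ndarray,
                   B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (a, b) in the (t, u) form to the (t, h) total/direct-effect form.

    The linear predictor t a_raw' + u b_raw' with u = tB + h equals
    t (a_raw + B b_raw)' + h b_raw', so a_tilde = a_raw + B b_raw and
    b_tilde = b_raw.
    """
    a_raw = np.asarray(a_raw, float).reshape(-1)
    b_raw = np.asarray(b_raw, float).reshape(-1)
    B = np.asarray(B, float)
    Bd = np.diag(B) if B.ndim == 2 else B.reshape(-1)
    if not (a_raw.shape == b_raw.shape == Bd.shape):
        raise ValueError("a, b and diag(B) must have equal length")
    return a_raw + Bd * b_raw, b_raw.copy()


def canonicalize_signs(params: ModelParams) -> ModelParams:
    """Resolve the sign indeterminacy to a deterministic canonical form.

    Component-wise: first make B positive by flipping u (C column, b entry,
    B sign), then make the largest-|entry| of each W column positive by
    flipping (t, u) jointly (W, C columns and a, b entries).  Specific
    loading columns are flipped independently.  The implied covariance of
    (x, y, z) is unchanged; ties at the largest entry go to the first index.
    """
    out = params.copy()
    for k in range(out.W.shape[1]):
        if out.B[k] < 0:
            out.C[:, k] *= -1.0
            out.b[k] *= -1.0
            out.B[k] *= -1.0
        i = int(np.argmax(np.abs(out.W[:, k])))
        if out.W[i, k] < 0:
            out.W[:, k] *= -1.0
            out.C[:, k] *= -1.0
            out.a[k] *= -1.0
            out.b[k] *= -1.0
    for M in (out.Wperp, out.Cperp):
        for k in range(M.shape[1]):
            i = int(np.argmax(np.abs(M[:, k])))
            if M[i, k] < 0:
                M[:, k] *= -1.0
    return out


def sort_components(params: ModelParams) -> ModelParams:
    """Reorder joint components so diag(Sigma_t B) is decreasing."""
    out = params.copy()
    order = np.argsort(-(out.sigma_t * out.B), kind="stable")
    for name in ("B", "sigma_t", "sigma_h", "a", "b"):
        setattr(out, name, getattr(out, name)[order])
    out.W = out.W[:, order]
    out.C = out.C[:, order]
    return out


_MATS = ("W", "C", "Wperp", "Cperp")
_VECS = ("B", "sigma_t", "sigma_tperp", "sigma_uperp", "sigma_h", "a", "b")


def save_params(params: ModelParams, directory) -> None:
    """Write one TSV per loading matrix plus a JSON manifest.

    Floats are serialized with 17 significant digits so that write -> read
    round-trips bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _MATS:
        M = getattr(params, name)
        header = "\t".join(f"comp{j + 1}" for j in range(M.shape[1]))
        np.savetxt(directory / f"{name}.tsv", M, fmt="%.17g",
                   delimiter="\t", header=header, comments="")
    d = params.dims
    manifest = {
        "format": "glmpo2pls-params-v1",
        "dims": {"p": d.p, "q": d.q, "K": d.K, "Kx": d.Kx, "Ky": d.Ky},
        "family": params.family,
        "a0": params.a0,
        "sigma_e2": params.sigma_e2,
        "sigma_f2": params.sigma_f2,
        "sigma_g2": params.sigma_g2,
        **{name: getattr(params, name).tolist() for name in _VECS},
    }
    (directory / "params.json").write_text(json.dumps(manifest, indent=1))


def load_params(directory) -> ModelParams:
    directory = Path(directory)
    manifest = json.loads((directory / "params.json").read_text())
    mats = {name: np.loadtxt(directory / f"{name}.tsv", delimiter="\t",
                             skiprows=1, ndmin=2) for name in _MATS}
    return ModelParams(
        **mats,
        **{name: np.asarray(manifest[name], float) for name in _VECS},
        family=manifest["family"], a0=manifest["a0"],
        sigma_e2=manifest["sigma_e2"], sigma_f2=manifest["sigma_f2"],
        sigma_g2=manifest["sigma_g2"],
    )


def params_factor(params: ModelParams, include_z: bool = True):
    """(L, D, r) low-rank factorization of Sigma_theta; see _gaussian."""
    if include_z and params.family != "gaussian":
        raise ValueError("full (x, y, z) factorization exists only for the "
                         "gaussian family")
    return loading_factor(params, include_z=include_z)
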