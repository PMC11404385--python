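"""Eigenvalue scree utilities for choosing component counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScreeResult:
    """Sorted spectra for the joint and block-specific structure.

    ``joint`` holds the singular values of x'y; ``x_specific`` and
    ``y_specific`` the eigenvalues of x'x resp. y'y after removing the
    suggested joint part.  ``suggested`` maps {"K", "Kx", "Ky"} to the
    largest-successive-ratio-drop counts (advisory only).
    """

    joint: np.ndarray
    x_specific: np.ndarray
    y_specific: np.ndarray
    suggested: dict


def _drop_suggestion(values: np.ndarray) -> int:
    v = np.asarray(values, float)
    v = v[v > 1e-12 * max(v[0], 1.0)]
    if v.size < 2:
        return max(int(v.size), 1)
    ratios = v[:-1] / v[1:]
    return int(np.argmax(ratios)) + 1


def _gram_eigvals(A: np.ndarray) -> np.ndarray:
    """Nonzero-part eigenvalues of A'A via the N x N Gram trick."""
    n, p = A.shape
    G = A @ A.T if n <= p else A.T @ A
    w = np.linalg.eigvalsh(G)[::-1]
    return np.clip(w, 0.0, None)


def scree(x, y) -> ScreeResult:
    """Spectra of x'y, x'x and y'y for scree inspection.

    Inputs must be column-centered.  Large blocks never form a p x p
    product: x'x eigenvalues come from the N x N Gram matrix and the
    specific spectra are computed after deflating the suggested joint part.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    if x.shape[0] < 2:
        raise ValueError("at least two samples are required")
    M = x.T @ y
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    K = _drop_suggestion(s)
    Ex = x - (x @ U[:, :K]) @ U[:, :K].T
    Ey = y - (y @ Vt[:K].T) @ Vt[:K]
    ex = _gram_eigvals(Ex)
    ey = _gram_eigvals(Ey)
    return ScreeResult(
        joint=s, x_specific=ex, y_specific=ey,
        suggested={"K": K, "Kx": _drop_suggestion(ex),
                   "Ky": _drop_suggestion(ey)},
    )
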