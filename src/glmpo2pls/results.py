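"""Fit-result container and its on-disk manifest format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParams, load_params, save_params


@dataclass
class FitResult:
    """Converged parameters plus the optimization trace and centering stats."""

    params: ModelParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    tol_used: float
    x_mean: np.ndarray = field(default=None)
    y_mean: np.ndarray = field(default=None)
    z_mean: float = 0.0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def family(self) -> str:
        return self.params.family


def save_fit(fit: FitResult, directory) -> None:
    """Parameter TSVs (see save_params) plus a fit manifest in JSON."""
    directory = Path(directory)
    save_params(fit.params, directory)
    manifest = {
        "format": "glmpo2pls-fit-v1",
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "tol_used": fit.tol_used,
        "loglik_trace": np.asarray(fit.loglik_trace).tolist(),
        "x_mean": None if fit.x_mean is None else np.asarray(fit.x_mean).tolist(),
        "y_mean": None if fit.y_mean is None else np.asarray(fit.y_mean).tolist(),
        "z_mean": fit.z_mean,
    }
    (directory / "fit.json").write_text(json.dumps(manifest, indent=1))


def load_fit(directory) -> FitResult:
    directory = Path(directory)
    m = json.loads((directory / "fit.json").read_text())
    return FitResult(
        params=load_params(directory),
        loglik_trace=np.asarray(m["loglik_trace"], float),
        n_iter=m["n_iter"], converged=m["converged"], tol_used=m["tol_used"],
        x_mean=None if m["x_mean"] is None else np.asarray(m["x_mean"], float),
        y_mean=None if m["y_mean"] is None else np.asarray(m["y_mean"], float),
        z_mean=m["z_mean"],
    )
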