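"""Delimited-text readers/writers and the aligned data bundle.

Canonical dialect: TSV with a header row of feature names and the first
column holding sample identifiers; CSV is accepted on read (chosen by file
extension).  All numeric output is serialized at 17 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric values in column(s) {bad}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"{path}: missing values are not supported "
                         f"(first offending samples: {rows})")
    return df


@dataclass
class DataBundle:
    """Sample-aligned (x, y, z) with centering statistics."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_ids: list
    x_features: list
    y_features: list
    family: str
    x_mean: np.ndarray
    y_mean: np.ndarray
    z_mean: float


def read_bundle(x_path, y_path, z_path, family: str = "gaussian") -> DataBundle:
    """Read and align the three tables; samples are reordered to x's order.

    Raises on ID mismatches (listing offenders), non-numeric cells, missing
    values, and mis-coded binary outcomes.
    """
    xf = _read_table(x_path)
    yf = _read_table(y_path)
    zf = _read_table(z_path)
    ids = xf.index
    for name, df in (("y", yf), ("z", zf)):
        missing = ids.difference(df.index).tolist()
        extra = df.index.difference(ids).tolist()
        if missing or extra:
            raise ValueError(
                f"sample IDs of {name} do not match x "
                f"(missing: {missing[:5]}, unexpected: {extra[:5]})")
    yf = yf.loc[ids]
    zf = zf.loc[ids]
    z = zf.iloc[:, 0].to_numpy(float)
    if family == "bernoulli":
        bad = sorted(set(np.unique(z)) - {0.0, 1.0})
        if bad:
            raise ValueError(f"bernoulli outcome must be coded 0/1; found {bad}")
    x = xf.to_numpy(float)
    y = yf.to_numpy(float)
    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    z_mean = float(z.mean()) if family == "gaussian" else 0.0
    return DataBundle(
        x=x - x_mean, y=y - y_mean, z=z - z_mean,
        sample_ids=ids.tolist(),
        x_features=xf.columns.tolist(), y_features=yf.columns.tolist(),
        family=family, x_mean=x_mean, y_mean=y_mean, z_mean=z_mean,
    )


def write_matrix(path, values: np.ndarray, sample_ids, feature_names) -> None:
    df = pd.DataFrame(np.atleast_2d(values), index=sample_ids,
                      columns=feature_names)
    df.index.name = "sample"
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def write_vector(path, values: np.ndarray, sample_ids, name: str = "z") -> None:
    write_matrix(path, np.asarray(values).reshape(-1, 1), sample_ids, [name])
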