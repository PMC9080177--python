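"""Delimited-text input/output for datasets, bases, and run reports.

Conventions: tab-separated values, header row required for the predictor
matrix, UTF-8, decimal point.  Bases are written with predictors as rows
and directions as columns; run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sir import Dataset


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a numeric samples-by-predictors table with a header row."""
    df = pd.read_csv(path, sep=sep)
    bad = [c for c in df.columns
           if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        for c in bad:
            coerced = pd.to_numeric(df[c], errors="coerce")
            culprit = df.index[coerced.isna() & df[c].notna()]
            if len(culprit):
                raise ValueError(
                    f"non-numeric cell in column {c!r} at data line "
                    f"{int(culprit[0]) + 2} of {path}")
        raise ValueError(f"non-numeric columns {bad} in {path}")
    if df.isna().any().any():
        line = int(df.index[df.isna().any(axis=1)][0]) + 2
        raise ValueError(f"missing value at data line {line} of {path}")
    return df


def read_dataset(x_path, y_path=None, response: str | None = None,
                 kind: str | None = None, sep: str = "\t") -> Dataset:
    """Assemble a Dataset from a predictor table and a response.

    The response comes either from ``y_path`` (single-column file,
    header optional) or from the named column ``response`` of the
    predictor table.  ``kind`` defaults to "continuous" for numeric
    responses and "categorical" otherwise.
    """
    X = read_matrix(x_path, sep=sep) if response is None else pd.read_csv(
        x_path, sep=sep)
    if response is not None:
        if response not in X.columns:
            raise ValueError(f"response column {response!r} not found in "
                             f"{x_path}; available: {list(X.columns)}")
        y = X[response].to_numpy()
        X = X.drop(columns=[response])
        bad = [c for c in X.columns
               if not np.issubdtype(X[c].dtype, np.number)]
        if bad:
            raise ValueError(f"non-numeric predictor columns {bad}")
    elif y_path is not None:
        ys = pd.read_csv(y_path, sep=sep, header=None).iloc[:, 0]
        if isinstance(ys.iloc[0], str):
            try:
                float(ys.iloc[0])
            except ValueError:
                ys = ys.iloc[1:]  # header line
        y = ys.to_numpy()
    else:
        raise ValueError("supply y_path or a response column name")
    if kind is None:
        try:
            y = np.asarray(y, dtype=float)
            kind = "continuous"
        except (TypeError, ValueError):
            kind = "categorical"
    return Dataset(X=X.to_numpy(dtype=float), y=np.asarray(y),
                   response_kind=kind)


def write_matrix(path, M: np.ndarray, columns=None) -> None:
    M = np.atleast_2d(np.asarray(M))
    if columns is None:
        columns = [f"v{j + 1}" for j in range(M.shape[1])]
    pd.DataFrame(M, columns=columns).to_csv(path, sep="\t", index=False)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
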