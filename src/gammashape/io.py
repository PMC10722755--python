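"""Dataset input and result serialization.

CSV or TSV in (dialect chosen by file extension), JSON and plain-text
coefficient tables out.  Missing values are rejected outright — imputation
is out of scope for a distributional model of strictly positive outcomes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import FitResult

__all__ = ["read_dataset", "fit_result_table", "write_json"]


def read_dataset(
    path, outcome_name: str, covariate_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Read a delimited table and build (y, design, column_names).

    The design holds the named covariates in the declared order with an
    explicit intercept column appended last.  Raises on missing columns,
    missing values (with row indices) and non-positive outcomes (with rows).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    wanted = [outcome_name, *covariate_names]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise KeyError(
            f"column(s) {missing} not found in {path.name}; "
            f"available: {list(df.columns)}"
        )
    sub = df[wanted]
    na_rows = sub.index[sub.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(
            f"missing values in rows (0-based) {na_rows[:20]}; "
            "remove or handle them before fitting"
        )
    y = sub[outcome_name].to_numpy(dtype=float)
    bad = np.nonzero(y <= 0)[0]
    if bad.size:
        raise ValueError(
            f"outcome {outcome_name!r} must be strictly positive; offending "
            f"rows (0-based): {bad[:20].tolist()}"
        )
    X = np.column_stack(
        [sub[c].to_numpy(dtype=float) for c in covariate_names]
        + [np.ones(len(sub))]
    )
    names = tuple(covariate_names) + ("const",)
    return y, X, names


def fit_result_table(fit: FitResult) -> str:
    """Plain-text coefficient table for a fitted model."""
    names = fit.spec.parameter_names()
    params = fit.params
    se = fit.standard_errors
    lines = [
        f"gamma {fit.spec.parameterization} model "
        f"(n={fit.n_observations}, loglik={fit.loglik:.4f}, "
        f"converged={fit.converged})",
        f"{'parameter':<16}{'estimate':>14}{'std. error':>14}",
    ]
    for name, b, s in zip(names, params, se):
        lines.append(f"{name:<16}{b:>14.6f}{s:>14.6f}")
    return "\n".join(lines)


def write_json(obj: dict, path) -> None:
    """Serialize to JSON at full float precision (repr round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
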