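"""Phenotype/covariate tables and fit reports.

Phenotype tables are delimited text (TSV/CSV autodetected) with a
header: an individual id column, a phenotype column, and any further
columns as covariates.  Ids are matched to tree-sequence individuals by
value (integer individual ids) and rows may come in any order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["load_phenotypes", "write_fit_report", "write_predictions"]


def load_phenotypes(
    path: str | Path, num_individuals: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read ``(y, X, ids)`` from a delimited text table.

    The first column is the individual id, the second the phenotype,
    remaining columns are covariates; an intercept column is prepended
    when no constant column is present.  Rows are sorted by id.  Missing
    or non-numeric phenotypes abort with the offending ids listed.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least id and phenotype columns")
    ids = df.iloc[:, 0].to_numpy()
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(y))[0]
    if bad.size:
        raise ValueError(
            f"{path}: missing/non-numeric phenotype for ids "
            f"{[ids[i] for i in bad[:10]]}"
        )
    order = np.argsort(ids, kind="stable")
    ids = np.asarray(ids[order], dtype=np.int64)
    y = y[order]
    if num_individuals is not None:
        out = np.nonzero((ids < 0) | (ids >= num_individuals))[0]
        if out.size:
            raise ValueError(
                f"{path}: ids not present in the tree sequence: "
                f"{ids[out[:10]].tolist()}"
            )
    if np.unique(ids).size != ids.size:
        raise ValueError(f"{path}: duplicate individual ids")
    if df.shape[1] > 2:
        X = df.iloc[:, 2:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)[order]
        if not np.any(np.ptp(X, axis=0) == 0):
            X = np.column_stack([np.ones(len(y)), X])
    else:
        X = np.ones((len(y), 1))
    return y, X, ids


def write_fit_report(fit, path: str | Path, extra: dict | None = None) -> None:
    report = fit.report()
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_predictions(result, path: str | Path, sep: str = "\t") -> None:
    """Predictions as delimited text: individual id, g_hat, optional SE."""
    cols = {"individual": result.target_index, "g_hat": result.predicted}
    if result.conditional_variance is not None:
        var = result.conditional_variance
        diag = np.diag(var) if var.ndim == 2 else var
        cols["se"] = np.sqrt(np.maximum(diag, 0.0))
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
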