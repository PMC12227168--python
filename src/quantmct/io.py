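"""File input/output: long-format CSV reading and result serialization."""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .estimation import GroupedSample
from .inference import TestResult

__all__ = ["read_long_csv", "result_to_tsv", "result_to_json", "read_result_tsv"]

logger = logging.getLogger("quantmct")


def read_long_csv(path, group_col: str = "group", value_col: str = "value",
                  order=None) -> GroupedSample:
    """Read one-observation-per-row data into a :class:`GroupedSample`.

    Groups are ordered by first appearance unless ``order`` is given.  Rows
    with missing or non-numeric values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    for col in (group_col, value_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    vals = pd.to_numeric(df[value_col], errors="coerce")
    bad = vals.isna() | ~np.isfinite(vals.fillna(np.nan))
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing/non-numeric values", n_dropped)
    df = df.loc[~bad]
    vals = vals[~bad]
    names = list(pd.unique(df[group_col])) if order is None else list(order)
    if len(names) < 2:
        raise ValueError("at least two groups required")
    samples = []
    for g in names:
        x = vals[df[group_col] == g].to_numpy(dtype=float)
        if x.size == 0:
            raise ValueError(f"group {g!r} has no observations")
        samples.append(x)
    return GroupedSample(samples, labels=[str(g) for g in names])


def _provenance_lines(result: TestResult) -> list:
    return [
        f"# method={result.method} cov_method={result.cov_method}",
        f"# alternative={result.alternative} direction={result.direction} "
        f"alpha={result.alpha:g}",
        f"# n={result.n} sizes={','.join(map(str, result.sizes))} "
        f"n_resamples={result.n_resamples} seed={result.seed}",
        f"# global_reject={result.reject_global}",
    ]


def result_to_tsv(result: TestResult, path) -> None:
    """Write the per-contrast table as TSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(result)) + "\n")
        result.to_frame().to_csv(fh, sep="\t", index=False)


def read_result_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def result_to_json(result: TestResult, path=None):
    """Machine-readable result dump (returns the dict if ``path`` is None)."""
    frame = result.to_frame()
    payload = {
        "method": result.method,
        "cov_method": result.cov_method,
        "alternative": result.alternative,
        "direction": result.direction,
        "alpha": result.alpha,
        "n": int(result.n),
        "sizes": [int(s) for s in result.sizes],
        "n_resamples": int(result.n_resamples),
        "seed": result.seed,
        "global_reject": bool(result.reject_global),
        "contrasts": frame.replace({np.inf: "inf", -np.inf: "-inf"}).to_dict("records"),
    }
    if path is None:
        return payload
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
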