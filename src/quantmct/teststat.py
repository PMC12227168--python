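"""Studentized contrast statistics and their estimated correlation.

For each contrast row ``h_l`` with constant ``eps_l`` the statistic is

    T_n(h_l, eps_l) = sqrt(n) * (h_l' q_hat - eps_l) / sqrt(h_l' Sigma_hat h_l),

asymptotically standard normal under the corresponding local null.  Jointly
the vector of statistics converges to ``N(0, R)`` with correlation matrix
``R = D H Sigma H' D`` and ``D = diag((h_l' Sigma h_l)^(-1/2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrasts import ContrastFamily, QuantileSpec
from .estimation import (
    CovarianceEstimate,
    EstimationError,
    GroupedSample,
    QuantileEstimates,
    pooled_quantile_vector,
)

__all__ = [
    "StatisticsBundle",
    "contrast_variances",
    "studentized_contrasts",
    "estimated_correlation",
]


@dataclass
class StatisticsBundle:
    statistics: np.ndarray     # (r,) studentized statistics T_n(h_l, eps_l)
    scale: np.ndarray          # (r,) sqrt(h_l' Sigma_hat h_l)
    correlation: np.ndarray    # (r, r) estimated limit correlation R_hat
    quantiles: QuantileEstimates
    n: int
    margins: np.ndarray        # the eps used


def contrast_variances(family: ContrastFamily, cov: CovarianceEstimate) -> np.ndarray:
    """``h_l' Sigma_hat h_l`` per row, using the block structure (no k*m matrix)."""
    m = family.m
    rows = family.matrix.reshape(family.r, family.k, m)
    out = np.zeros(family.r)
    for i, block in enumerate(cov.blocks):
        hi = rows[:, i, :]  # (r, m)
        out += np.einsum("ra,ab,rb->r", hi, block, hi)
    return out


def studentized_contrasts(gs: GroupedSample, spec: QuantileSpec,
                          family: ContrastFamily, cov: CovarianceEstimate,
                          margins=None) -> StatisticsBundle:
    """Compute the studentized statistics and correlation for a contrast family."""
    if family.m != spec.m:
        raise ValueError("contrast family and quantile spec disagree on m")
    if family.k != gs.k:
        raise ValueError("contrast family and sample disagree on the group count")
    eps = family.margins if margins is None else \
        np.broadcast_to(np.asarray(margins, dtype=float), (family.r,))
    qhat = pooled_quantile_vector(gs, spec)
    var = contrast_variances(family, cov)
    bad = np.where(var <= 0)[0]
    if bad.size:
        names = ", ".join(family.row_labels[i] for i in bad)
        raise EstimationError(f"non-positive studentizer for contrast(s): {names}")
    scale = np.sqrt(var)
    stats_vec = np.sqrt(gs.n) * (family.matrix @ qhat.values - eps) / scale
    corr = estimated_correlation(family, cov, _var=var)
    return StatisticsBundle(
        statistics=stats_vec, scale=scale, correlation=corr,
        quantiles=qhat, n=gs.n, margins=np.array(eps, dtype=float),
    )


def estimated_correlation(family: ContrastFamily, cov: CovarianceEstimate,
                          _var=None) -> np.ndarray:
    """``D_hat H Sigma_hat H' D_hat``: unit diagonal by construction."""
    var = contrast_variances(family, cov) if _var is None else _var
    if np.any(var <= 0):
        raise EstimationError("non-positive studentizer in correlation computation")
    H = family.matrix
    hsh = H @ cov.full @ H.T
    d = 1.0 / np.sqrt(var)
    corr = d[:, None] * hsh * d[None, :]
    np.fill_diagonal(corr, 1.0)
    return corr
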