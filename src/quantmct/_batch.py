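"""Vectorized kernels for resampling engines (internal).

Permutation and bootstrap critical values need the full quantile/covariance
pipeline re-run on hundreds to thousands of resampled data sets.  The helpers
here operate on a batch axis: each group's resampled observations are a
``(B, n_i)`` array, and quantiles, covariance blocks, and studentized contrast
statistics come out with a leading replicate axis.  Formulas match the scalar
implementations in :mod:`quantmct.estimation` / :mod:`quantmct.teststat`
exactly; consistency is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .estimation import quantile_index

_SQRT2PI = math.sqrt(2.0 * math.pi)


def batch_quantiles(x: np.ndarray, probs) -> np.ndarray:
    """Empirical quantiles per replicate row.  ``x``: (B, n_i) -> (B, m)."""
    xs = np.sort(x, axis=1)
    cols = [quantile_index(x.shape[1], p) for p in probs]
    return xs[:, cols]


def _blocks_from_densities(dens: np.ndarray, probs: np.ndarray,
                           kappa_inv: float) -> np.ndarray:
    """(B, m) density values -> (B, m, m) covariance blocks."""
    pa = probs[:, None]
    pb = probs[None, :]
    numer = np.minimum(pa, pb) - pa * pb  # (m, m)
    return kappa_inv * numer[None] / (dens[:, :, None] * dens[:, None, :])


def batch_kernel_block(x: np.ndarray, probs: np.ndarray, n_total: int):
    """Kernel-route covariance blocks for one group.

    Returns ``(blocks, valid)`` with blocks (B, m, m); replicates with a
    non-finite or non-positive density are flagged invalid.
    """
    B, ni = x.shape
    xs = np.sort(x, axis=1)
    sd = xs.std(axis=1, ddof=1)
    q25, q75 = np.quantile(xs, [0.25, 0.75], axis=1)
    spread = np.minimum(sd, (q75 - q25) / 1.34)
    spread = np.where(spread > 0, spread, sd)
    spread = np.where(spread > 0, spread, 1.0)  # constant replicate fallback
    h = 0.9 * ni ** (-0.2) * spread
    cols = [quantile_index(ni, p) for p in probs]
    q = xs[:, cols]  # (B, m)
    dens = np.empty_like(q)
    for j in range(q.shape[1]):
        z = (q[:, j:j + 1] - xs) / h[:, None]
        dens[:, j] = np.exp(-0.5 * z * z).mean(axis=1) / (h * _SQRT2PI)
    valid = np.all(np.isfinite(dens) & (dens > 0), axis=1)
    dens_safe = np.where(dens > 0, dens, 1.0)
    return _blocks_from_densities(dens_safe, probs, n_total / ni), valid


def batch_interval_block(x: np.ndarray, probs: np.ndarray, n_total: int,
                         gamma: float = 0.05):
    """Interval-route covariance blocks for one group (ties -> invalid)."""
    B, ni = x.shape
    z = float(stats.norm.ppf(1.0 - gamma / 2.0))
    xs = np.sort(x, axis=1)
    m = len(probs)
    inv_dens = np.empty((B, m))
    valid = np.ones(B, dtype=bool)
    for j, p in enumerate(probs):
        lam = z * math.sqrt(ni * p * (1.0 - p))
        lo = max(math.ceil(ni * p - lam), 1)
        hi = min(math.ceil(ni * p + lam), ni)
        if lo >= hi:
            valid[:] = False
            inv_dens[:, j] = 1.0
            continue
        spread = xs[:, hi - 1] - xs[:, lo - 1]
        valid &= spread > 0
        inv_dens[:, j] = np.where(spread > 0, ni * spread / (2.0 * lam), 1.0)
    return _blocks_from_densities(1.0 / inv_dens, probs, n_total / ni), valid


def batch_bootstrap_block(x: np.ndarray, probs: np.ndarray, n_total: int,
                          n_boot: int, rng: np.random.Generator,
                          max_elems: int = 40_000_000):
    """Bootstrap-route covariance blocks for one group.

    Each replicate row is itself resampled ``n_boot`` times (nested resampling);
    chunked over the batch axis to bound memory.
    """
    B, ni = x.shape
    m = len(probs)
    cols = [quantile_index(ni, p) for p in probs]
    blocks = np.empty((B, m, m))
    valid = np.ones(B, dtype=bool)
    chunk = max(1, int(max_elems / (n_boot * ni)))
    for start in range(0, B, chunk):
        sl = slice(start, min(start + chunk, B))
        xb = x[sl]  # (c, ni)
        c = xb.shape[0]
        idx = rng.integers(0, ni, size=(c, n_boot, ni))
        res = np.sort(np.take_along_axis(xb[:, None, :], idx, axis=2), axis=2)
        qstar = res[:, :, cols]  # (c, n_boot, m)
        centered = qstar - qstar.mean(axis=1, keepdims=True)
        cov = np.einsum("cba,cbd->cad", centered, centered) / (n_boot - 1)
        blocks[sl] = n_total * cov
    diag = np.einsum("bii->bi", blocks)
    valid &= np.all(diag > 0, axis=1)
    return blocks, valid


def batch_cov_blocks(group_arrays, probs, n_total, method, *, gamma=0.05,
                     n_boot=2000, rng=None):
    """Covariance blocks per group for a batch of resampled data sets.

    Returns ``(blocks_per_group, valid)``: a list of (B, m, m) arrays and the
    conjunction of the per-group validity masks.
    """
    probs = np.asarray(probs, dtype=float)
    blocks, valid = [], None
    for x in group_arrays:
        if method == "kernel":
            blk, ok = batch_kernel_block(x, probs, n_total)
        elif method == "interval":
            blk, ok = batch_interval_block(x, probs, n_total, gamma=gamma)
        elif method == "bootstrap":
            blk, ok = batch_bootstrap_block(x, probs, n_total, n_boot, rng)
        else:
            raise ValueError(f"unknown covariance method {method!r}")
        blocks.append(blk)
        valid = ok if valid is None else (valid & ok)
    return blocks, valid


def batch_contrast_stats(qmat: np.ndarray, blocks, family, n_total: int,
                         center=None):
    """Studentized contrast statistics per replicate.

    ``qmat``: (B, k*m) quantile vectors; ``blocks``: list of (B, m, m).
    ``center``: optional (k*m,) vector subtracted from each quantile vector
    (the observed ``q_hat`` for bootstrap counterparts; omit for permutation).
    Returns ``(T, valid)`` with T of shape (B, r).
    """
    rows = family.matrix.reshape(family.r, family.k, family.m)
    B = qmat.shape[0]
    var = np.zeros((B, family.r))
    for i, blk in enumerate(blocks):
        hi = rows[:, i, :]  # (r, m)
        var += np.einsum("bxy,rx,ry->br", blk, hi, hi)
    q = qmat if center is None else qmat - np.asarray(center)[None, :]
    numer = q @ family.matrix.T  # (B, r)
    valid = np.all(np.isfinite(var) & (var > 0), axis=1)
    var_safe = np.where(var > 0, var, 1.0)
    T = math.sqrt(n_total) * numer / np.sqrt(var_safe)
    valid &= np.all(np.isfinite(T), axis=1)
    return T, valid
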