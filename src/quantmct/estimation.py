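"""Empirical quantiles and estimators of their asymptotic covariance.

For ``k`` mutually independent samples with sizes ``n_i`` (total ``n``) and
probabilities ``p_1 < ... < p_m``, the centred and scaled quantile estimates
``sqrt(n) * (q_hat - q)`` are asymptotically normal with block-diagonal
covariance ``Sigma = diag(Sigma^(1), ..., Sigma^(k))`` where

    Sigma^(i)_ab = (n / n_i) * (min(p_a, p_b) - p_a * p_b)
                   / (f_i(q_ia) * f_i(q_ib)),

``f_i`` being the group density.  The density values at the quantiles are the
only unknown ingredient; this module provides three plug-in routes:

* ``kernel`` -- Gaussian kernel density estimate with Silverman's
  rule-of-thumb bandwidth ``0.9 * n_i^(-1/5) * min(SD, IQR/1.34)``;
* ``bootstrap`` -- groupwise with-replacement resampling of the quantile
  vector, ``Sigma^(i) = n * Cov_boot(q_hat*^(i))``;
* ``interval`` -- an order-statistic spacing around each quantile estimates
  ``1/f_i(q_ij)`` directly.

All three are consistent under a positive, continuous density at each target
quantile; ties in the data are treated as an error rather than silently
floored, since heavy ties contradict that assumption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .contrasts import QuantileSpec

__all__ = [
    "EstimationError",
    "GroupedSample",
    "QuantileEstimates",
    "CovarianceEstimate",
    "quantile_index",
    "empirical_quantile",
    "pooled_quantile_vector",
    "bandwidth_rule",
    "density_at_quantile_kernel",
    "cov_kernel",
    "cov_bootstrap",
    "cov_interval",
    "estimate_covariance",
]

COV_METHODS = ("kernel", "bootstrap", "interval")


class EstimationError(ValueError):
    """Raised when a quantity needed for inference is degenerate."""


@dataclass
class GroupedSample:
    """``k`` independent groups of real-valued observations."""

    groups: list
    labels: list = None

    def __post_init__(self):
        self.groups = [np.asarray(g, dtype=float).reshape(-1) for g in self.groups]
        if len(self.groups) < 1:
            raise ValueError("at least one group is required")
        for i, g in enumerate(self.groups):
            if g.size < 1:
                raise ValueError(f"group {i + 1} is empty")
            if not np.all(np.isfinite(g)):
                raise ValueError(f"group {i + 1} contains non-finite values")
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(len(self.groups))]
        if len(self.labels) != len(self.groups):
            raise ValueError("labels must match groups in length")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.groups])

    @property
    def n(self) -> int:
        return int(self.sizes.sum())

    @property
    def kappa(self) -> np.ndarray:
        """Group share estimates ``n_i / n``."""
        return self.sizes / self.n

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.groups)


@dataclass
class QuantileEstimates:
    """Group-major pooled vector of empirical quantiles."""

    values: np.ndarray  # (k*m,)
    spec: QuantileSpec

    def by_group(self, k: int) -> np.ndarray:
        return self.values.reshape(k, self.spec.m)


@dataclass
class CovarianceEstimate:
    """Block-diagonal estimate of the asymptotic covariance of sqrt(n)(q_hat - q)."""

    blocks: list  # k matrices, each (m, m)
    method: str
    density_values: np.ndarray = None  # (k, m) estimated f_i(q_ij), when used
    settings: dict = field(default_factory=dict)
    seed: int = None

    def __post_init__(self):
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        for i, b in enumerate(self.blocks):
            if b.ndim != 2 or b.shape[0] != b.shape[1]:
                raise ValueError(f"block {i + 1} is not square")
            if not np.allclose(b, b.T, atol=1e-8):
                raise ValueError(f"block {i + 1} is not symmetric")
            if np.any(np.diag(b) <= 0):
                raise EstimationError(
                    f"covariance block for group {i + 1} has a non-positive "
                    "diagonal entry"
                )

    @property
    def full(self) -> np.ndarray:
        """The full block-diagonal matrix (direct sum of the group blocks)."""
        return linalg.block_diag(*self.blocks)


# ---------------------------------------------------------------------------
# quantiles
# ---------------------------------------------------------------------------

def quantile_index(n: int, p: float) -> int:
    """0-based order-statistic index of the left-continuous empirical quantile.

    The estimate is the ``ceil(n*p)``-th order statistic; a small epsilon
    guards against upward rounding of exact integer products.
    """
    idx = math.ceil(n * p - 1e-9)
    return min(max(idx, 1), n) - 1


def empirical_quantile(sample, p: float) -> float:
    """Left-continuous inverse of the empirical CDF, ``inf{u : F_hat(u) >= p}``."""
    x = np.asarray(sample, dtype=float).reshape(-1)
    if x.size == 0:
        raise ValueError("empty sample")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return float(np.sort(x)[quantile_index(x.size, p)])


def pooled_quantile_vector(gs: GroupedSample, spec: QuantileSpec) -> QuantileEstimates:
    """Group-major concatenation of empirical quantiles over (group, probability)."""
    vals = np.empty(gs.k * spec.m)
    for i, g in enumerate(gs.groups):
        xs = np.sort(g)
        for j, p in enumerate(spec.probabilities):
            vals[i * spec.m + j] = xs[quantile_index(g.size, p)]
    return QuantileEstimates(vals, spec)


# ---------------------------------------------------------------------------
# kernel route
# ---------------------------------------------------------------------------

def bandwidth_rule(sample) -> float:
    """Silverman rule-of-thumb bandwidth ``0.9 * n^(-1/5) * min(SD, IQR/1.34)``.

    Fallback chain for degenerate spreads: if ``min(SD, IQR/1.34) = 0`` use the
    SD alone; if the sample is constant (SD = 0) fall back to 1 with a warning.
    """
    x = np.asarray(sample, dtype=float).reshape(-1)
    if x.size < 2:
        raise ValueError("bandwidth rule needs at least two observations")
    sd = float(np.std(x, ddof=1))
    q25, q75 = np.quantile(x, [0.25, 0.75])  # interpolating, as in R's bw.nrd0
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0.0:
        spread = sd
    if spread <= 0.0:
        warnings.warn(
            "constant sample: falling back to bandwidth scale 1", RuntimeWarning
        )
        spread = 1.0
    return 0.9 * x.size ** (-0.2) * spread


def density_at_quantile_kernel(sample, at: float, bandwidth: float) -> float:
    """Gaussian kernel density estimate of the sample density at ``at``."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(sample, dtype=float).reshape(-1)
    z = (at - x) / bandwidth
    return float(np.exp(-0.5 * z * z).sum() / (x.size * bandwidth * math.sqrt(2.0 * math.pi)))


def _block_from_densities(dens: np.ndarray, probs: np.ndarray, kappa_inv: float) -> np.ndarray:
    """Assemble one group block from density values at the quantiles."""
    pa = probs[:, None]
    pb = probs[None, :]
    numer = np.minimum(pa, pb) - pa * pb
    return kappa_inv * numer / (dens[:, None] * dens[None, :])


def cov_kernel(gs: GroupedSample, spec: QuantileSpec) -> CovarianceEstimate:
    """Plug-in covariance with Gaussian-kernel density estimates."""
    probs = np.asarray(spec.probabilities)
    qhat = pooled_quantile_vector(gs, spec).by_group(gs.k)
    blocks, dens_all, bws = [], [], []
    for i, g in enumerate(gs.groups):
        try:
            h = bandwidth_rule(g)
        except ValueError as exc:
            raise EstimationError(f"group {gs.labels[i]}: {exc}") from exc
        if not np.isfinite(h) or h <= 0:
            raise EstimationError(f"group {gs.labels[i]}: degenerate bandwidth {h}")
        dens = np.array(
            [density_at_quantile_kernel(g, qhat[i, j], h) for j in range(spec.m)]
        )
        blocks.append(_block_from_densities(dens, probs, gs.n / g.size))
        dens_all.append(dens)
        bws.append(h)
    return CovarianceEstimate(
        blocks, "kernel", density_values=np.vstack(dens_all),
        settings={"bandwidths": bws},
    )


# ---------------------------------------------------------------------------
# bootstrap route
# ---------------------------------------------------------------------------

def cov_bootstrap(gs: GroupedSample, spec: QuantileSpec, n_boot: int = 2000,
                  seed=None) -> CovarianceEstimate:
    """Groupwise bootstrap covariance ``Sigma^(i) = n * Cov_boot(q_hat*^(i))``.

    Each group is resampled with replacement ``n_boot`` times; the empirical
    covariance of the resampled quantile vectors, scaled by the total sample
    size, estimates the group block.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    probs = spec.probabilities
    blocks = []
    for i, g in enumerate(gs.groups):
        ni = g.size
        idx = rng.integers(0, ni, size=(n_boot, ni))
        res = np.sort(g[idx], axis=1)
        cols = [quantile_index(ni, p) for p in probs]
        qstar = res[:, cols]  # (n_boot, m)
        block = gs.n * np.cov(qstar, rowvar=False, ddof=1).reshape(spec.m, spec.m)
        if np.any(np.diag(block) <= 0):
            raise EstimationError(
                f"group {gs.labels[i]}: bootstrap quantiles are constant; "
                "increase the group size or use another covariance estimator "
                "(heavy ties in the data?)"
            )
        blocks.append(block)
    return CovarianceEstimate(
        blocks, "bootstrap", settings={"n_boot": n_boot},
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# interval route
# ---------------------------------------------------------------------------

def cov_interval(gs: GroupedSample, spec: QuantileSpec, gamma: float = 0.05) -> CovarianceEstimate:
    """Order-statistic interval estimate of ``1/f_i(q_ij)`` plugged into the blocks.

    Around the target rank ``n_i * p_j`` a symmetric window of half-width
    ``lambda = z_{1-gamma/2} * sqrt(n_i * p_j * (1 - p_j))`` ranks is taken;
    the spacing of the bracketing order statistics divided by the probability
    width it covers estimates the reciprocal density:

        1 / f_hat = n_i * (X_(U) - X_(L)) / (2 * lambda).
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    z = float(stats.norm.ppf(1.0 - gamma / 2.0))
    probs = np.asarray(spec.probabilities)
    blocks, inv_dens_all = [], []
    for i, g in enumerate(gs.groups):
        ni = g.size
        xs = np.sort(g)
        inv_dens = np.empty(spec.m)
        for j, p in enumerate(probs):
            lam = z * math.sqrt(ni * p * (1.0 - p))
            lo = max(math.ceil(ni * p - lam), 1)
            hi = min(math.ceil(ni * p + lam), ni)
            if lo >= hi:
                raise EstimationError(
                    f"group {gs.labels[i]}: sample too small for the interval "
                    f"estimator at p={p:g}"
                )
            spread = xs[hi - 1] - xs[lo - 1]
            if spread <= 0.0:
                raise EstimationError(
                    f"group {gs.labels[i]}: tied order statistics at p={p:g}; "
                    "the interval estimator is undefined (the positive-density "
                    "assumption looks violated)"
                )
            inv_dens[j] = ni * spread / (2.0 * lam)
        blocks.append(_block_from_densities(1.0 / inv_dens, probs, gs.n / ni))
        inv_dens_all.append(inv_dens)
    return CovarianceEstimate(
        blocks, "interval", density_values=1.0 / np.vstack(inv_dens_all),
        settings={"gamma": gamma},
    )


def estimate_covariance(gs: GroupedSample, spec: QuantileSpec, method: str = "kernel",
                        **kwargs) -> CovarianceEstimate:
    """Dispatch to one of the covariance estimators by name."""
    if method == "kernel":
        return cov_kernel(gs, spec)
    if method == "bootstrap":
        return cov_bootstrap(gs, spec, **kwargs)
    if method == "interval":
        return cov_interval(gs, spec, **kwargs)
    raise ValueError(f"unknown covariance method {method!r}; choose from {COV_METHODS}")
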