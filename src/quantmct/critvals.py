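"""Critical values for the four simultaneous testing procedures.

Two Bonferroni-adjusted routes test each contrast at local level ``alpha/r``:

* ``bonf-asymptotic`` -- standard normal quantiles ``z_{1-alpha/(2r)}``
  (two-sided) or ``z_{1-alpha/r}`` (noninferiority);
* ``bonf-permutation`` -- a studentized permutation distribution: samples are
  redrawn without replacement from the pooled data, and both the quantiles and
  the covariance estimate are recomputed on every permuted data set.  The
  studentization is what keeps the procedure asymptotically valid when the
  group distributions differ; under exchangeability it is finitely exact.

Two max-t multiple contrast test procedures (MCTPs) use one common critical
value from the joint limit of the statistics:

* ``mctp-asymptotic`` -- Monte-Carlo quantile of ``max_l Y_l`` (or
  ``max_l |Y_l|``) with ``Y = D_hat H A Z``, ``A A' = Sigma_hat``;
* ``mctp-bootstrap`` -- groupwise with-replacement resampling of the
  studentized counterparts ``T*_l = sqrt(n) h_l'(q_hat* - q_hat) /
  sqrt(h_l' Sigma_hat* h_l)``.

Empirical quantiles of resampling distributions use the ``ceil(B*beta)``-th
order statistic throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._batch import batch_contrast_stats, batch_cov_blocks, batch_quantiles
from .contrasts import ContrastFamily, QuantileSpec
from .estimation import (
    CovarianceEstimate,
    EstimationError,
    GroupedSample,
    pooled_quantile_vector,
)
from .teststat import contrast_variances

__all__ = [
    "CriticalValues",
    "ResamplingDiagnostics",
    "METHODS",
    "crit_bonf_asymptotic",
    "crit_bonf_permutation",
    "crit_mctp_asymptotic",
    "crit_mctp_bootstrap",
    "resampling_quantile",
]

METHODS = ("bonf-asymptotic", "bonf-permutation", "mctp-asymptotic", "mctp-bootstrap")

ALTERNATIVES = ("two_sided", "noninferiority")

#: abort when more than this fraction of resampling replicates degenerates
MAX_DROP_FRACTION = 0.10


@dataclass
class ResamplingDiagnostics:
    attempted: int = 0
    dropped: int = 0

    @property
    def kept(self) -> int:
        return self.attempted - self.dropped


@dataclass
class CriticalValues:
    values: np.ndarray            # (r,) per-contrast critical values
    method: str
    alternative: str
    alpha: float
    draws: np.ndarray = None      # (kept, r) per-contrast draws (Bonferroni
                                  # resampling) or (kept,) max-draws (MCTPs)
    seed: object = None
    n_draws: int = 0              # B or M actually kept
    diagnostics: ResamplingDiagnostics = field(default_factory=ResamplingDiagnostics)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def resampling_quantile(draws: np.ndarray, beta: float, axis: int = 0) -> np.ndarray:
    """``ceil(B*beta)``-th order statistic along ``axis``."""
    b = draws.shape[axis]
    idx = min(max(math.ceil(b * beta - 1e-9), 1), b) - 1
    return np.take(np.sort(draws, axis=axis), idx, axis=axis)


def crit_bonf_asymptotic(alpha: float, r: int, alternative: str = "two_sided") -> CriticalValues:
    """Bonferroni-adjusted standard normal critical values."""
    _check_alpha(alpha)
    _check_alternative(alternative)
    if r < 1:
        raise ValueError("r must be at least 1")
    beta = 1.0 - alpha / (2 * r) if alternative == "two_sided" else 1.0 - alpha / r
    z = float(stats.norm.ppf(beta))
    return CriticalValues(np.full(r, z), "bonf-asymptotic", alternative, alpha)


def _permuted_groups(gs: GroupedSample, n_perm: int, rng: np.random.Generator):
    """Partition the pooled sample into groups of the original sizes, B times."""
    pooled = gs.pooled()
    n = pooled.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    xp = pooled[order]  # (B, n) random permutations of the pooled data
    out, start = [], 0
    for ni in gs.sizes:
        out.append(xp[:, start:start + ni])
        start += ni
    return out


def _stack_quantiles(group_arrays, probs) -> np.ndarray:
    return np.concatenate([batch_quantiles(x, probs) for x in group_arrays], axis=1)


def _finalize_resampling(T, valid, attempted):
    diag = ResamplingDiagnostics(attempted=attempted, dropped=int((~valid).sum()))
    if diag.dropped > MAX_DROP_FRACTION * attempted:
        raise EstimationError(
            f"{diag.dropped}/{attempted} resampling replicates degenerated; "
            "the data are too small or too heavily tied for this estimator"
        )
    return T[valid], diag


def crit_bonf_permutation(gs: GroupedSample, spec: QuantileSpec,
                          family: ContrastFamily, alpha: float = 0.05,
                          n_perm: int = 1999, seed=None,
                          cov_method: str = "kernel",
                          alternative: str = "two_sided",
                          cov_kwargs: dict = None) -> CriticalValues:
    """Studentized permutation critical values at local level ``alpha/r``.

    Per contrast ``l`` the critical value is the empirical
    ``(1 - alpha/r)``-quantile of the permuted ``|T^pi_l|`` (two-sided) or
    ``T^pi_l`` (noninferiority).  The covariance estimate is recomputed on
    every permuted data set with the same estimator used for the observed
    statistic.
    """
    _check_alpha(alpha)
    _check_alternative(alternative)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    cov_kwargs = dict(cov_kwargs or {})
    groups_p = _permuted_groups(gs, n_perm, rng)
    probs = np.asarray(spec.probabilities)
    qmat = _stack_quantiles(groups_p, probs)
    blocks, valid = batch_cov_blocks(groups_p, probs, gs.n, cov_method,
                                     rng=rng, **cov_kwargs)
    T, ok = batch_contrast_stats(qmat, blocks, family, gs.n)
    T, diag = _finalize_resampling(T, valid & ok, n_perm)
    beta = 1.0 - alpha / family.r
    draws = np.abs(T) if alternative == "two_sided" else T
    values = resampling_quantile(draws, beta, axis=0)
    return CriticalValues(values, "bonf-permutation", alternative, alpha,
                          draws=draws, seed=seed, n_draws=T.shape[0],
                          diagnostics=diag)


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """A factor A with A A' = Sigma; eigenvalue clipping for semidefinite input."""
    sym = 0.5 * (sigma + sigma.T)
    try:
        return np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sym)
        tol = 1e-8 * max(1.0, float(np.max(np.abs(w))))
        if np.min(w) < -tol:
            raise EstimationError(
                "covariance estimate is not positive semidefinite"
            ) from None
        return v * np.sqrt(np.clip(w, 0.0, None))


def crit_mctp_asymptotic(family: ContrastFamily, cov: CovarianceEstimate,
                         alpha: float = 0.05, alternative: str = "two_sided",
                         n_draws: int = 100_000, seed=None) -> CriticalValues:
    """Monte-Carlo max-t critical value from the estimated joint limit.

    Draws ``Y = D_hat H A Z`` with ``A`` a factor of the (block-diagonal)
    covariance estimate, so rank-deficient contrast families pose no problem;
    the common critical value is the ``(1 - alpha)``-quantile of
    ``max_l |Y_l|`` (two-sided) or ``max_l Y_l`` (noninferiority).
    """
    _check_alpha(alpha)
    _check_alternative(alternative)
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for a stable quantile")
    var = contrast_variances(family, cov)
    if np.any(var <= 0):
        raise EstimationError("non-positive studentizer in MCTP critical value")
    rng = np.random.default_rng(seed)
    A = _psd_factor(cov.full)
    z = rng.standard_normal((n_draws, A.shape[0]))
    Y = (z @ A.T) @ family.matrix.T / np.sqrt(var)[None, :]
    maxdraws = np.max(np.abs(Y), axis=1) if alternative == "two_sided" else np.max(Y, axis=1)
    value = float(resampling_quantile(maxdraws, 1.0 - alpha))
    return CriticalValues(np.full(family.r, value), "mctp-asymptotic", alternative,
                          alpha, draws=maxdraws, seed=seed, n_draws=n_draws,
                          diagnostics=ResamplingDiagnostics(n_draws, 0))


def _bootstrap_groups(gs: GroupedSample, n_boot: int, rng: np.random.Generator):
    out = []
    for g in gs.groups:
        idx = rng.integers(0, g.size, size=(n_boot, g.size))
        out.append(g[idx])
    return out


def crit_mctp_bootstrap(gs: GroupedSample, spec: QuantileSpec,
                        family: ContrastFamily, alpha: float = 0.05,
                        n_boot: int = 1999, seed=None,
                        cov_method: str = "kernel",
                        alternative: str = "two_sided",
                        cov_kwargs: dict = None) -> CriticalValues:
    """Groupwise-bootstrap max-t critical value.

    Each group is resampled with replacement; the bootstrap counterparts
    ``T*_l`` are centred at the observed quantile vector and studentized by
    the covariance estimate recomputed on the bootstrap sample.  When
    ``cov_method='bootstrap'`` an inner covariance bootstrap runs inside each
    outer replicate (nested resampling).
    """
    _check_alpha(alpha)
    _check_alternative(alternative)
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    cov_kwargs = dict(cov_kwargs or {})
    probs = np.asarray(spec.probabilities)
    qhat = pooled_quantile_vector(gs, spec).values
    groups_b = _bootstrap_groups(gs, n_boot, rng)
    qmat = _stack_quantiles(groups_b, probs)
    blocks, valid = batch_cov_blocks(groups_b, probs, gs.n, cov_method,
                                     rng=rng, **cov_kwargs)
    T, ok = batch_contrast_stats(qmat, blocks, family, gs.n, center=qhat)
    T, diag = _finalize_resampling(T, valid & ok, n_boot)
    maxdraws = np.max(np.abs(T), axis=1) if alternative == "two_sided" else np.max(T, axis=1)
    value = float(resampling_quantile(maxdraws, 1.0 - alpha))
    return CriticalValues(np.full(family.r, value), "mctp-bootstrap", alternative,
                          alpha, draws=maxdraws, seed=seed, n_draws=T.shape[0],
                          diagnostics=diag)
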