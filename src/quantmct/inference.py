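"""Complete multiple tests: decisions, adjusted p-values, simultaneous CIs.

The global hypothesis is the intersection of the local ones and is rejected
iff at least one local hypothesis is rejected (union-intersection principle);
by construction the same critical value drives both the local decision and the
corresponding simultaneous confidence bound, so a margin lies outside its
interval exactly when the contrast is rejected.

One-sided hypotheses come in two directions.  ``direction='greater'`` tests
``H0_l: h_l'q <= eps_l`` against ``h_l'q > eps_l``; ``direction='less'`` is
handled by negating rows and margins internally so that a single code path
exists, and the reported estimates and confidence bounds are mirrored back to
the user's scale (yielding ``(-inf, upper]`` intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import ContrastFamily, QuantileSpec
from .critvals import (
    CriticalValues,
    METHODS,
    crit_bonf_asymptotic,
    crit_bonf_permutation,
    crit_mctp_asymptotic,
    crit_mctp_bootstrap,
)
from .estimation import GroupedSample, estimate_covariance
from .teststat import StatisticsBundle, studentized_contrasts

__all__ = [
    "HypothesisSpec",
    "TestResult",
    "run_multiple_test",
    "run_equivalence_tost",
    "simultaneous_cis",
    "adjusted_p_values",
]

DEFAULT_N_RESAMPLES = 1999   # single-data-set analyses
DEFAULT_N_MC = 100_000       # Monte-Carlo draws for the asymptotic MCTP


@dataclass
class HypothesisSpec:
    """What is being tested: alternative type, direction, margins, level."""

    alternative: str = "two_sided"   # two_sided | noninferiority | equivalence
    direction: str = "greater"       # greater | less (one-sided families)
    margins: object = 0.0            # eps, scalar or length-r
    delta: object = None             # equivalence half-widths, > 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.alternative not in ("two_sided", "noninferiority", "equivalence"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.direction not in ("greater", "less"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.alternative == "equivalence":
            if self.delta is None:
                raise ValueError("equivalence testing requires delta")
            if np.any(np.asarray(self.delta, dtype=float) <= 0):
                raise ValueError("equivalence half-widths delta must be positive")


@dataclass
class TestResult:
    """Per-contrast and global outcome of a simultaneous quantile test."""

    row_labels: list
    estimates: np.ndarray        # h_l' q_hat on the user's scale
    margins: np.ndarray          # eps (or delta for equivalence)
    statistics: np.ndarray       # studentized statistics on the user's scale
    critical_values: np.ndarray
    reject: np.ndarray           # bool per contrast
    pvalues: np.ndarray          # multiplicity-adjusted
    pvalues_raw: np.ndarray      # per-contrast resampling p before Bonferroni
                                 # multiplication (equals pvalues for MCTPs)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reject_global: bool
    method: str
    cov_method: str
    alternative: str
    direction: str
    alpha: float
    n: int
    sizes: np.ndarray
    seed: object = None
    n_resamples: int = 0
    correlation: np.ndarray = None
    diagnostics: object = None
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast": self.row_labels,
                "estimate": self.estimates,
                "margin": self.margins,
                "statistic": self.statistics,
                "critical_value": self.critical_values,
                "p_adjusted": self.pvalues,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "reject": self.reject,
            }
        )


def simultaneous_cis(estimates, scale, n, crit_values, alternative,
                     direction="greater"):
    """Simultaneous confidence bounds dual to the test decisions.

    Two-sided: ``h'q_hat -+ sqrt(h'Sigma_hat h) * q_l / sqrt(n)``.
    Noninferiority (greater): ``[h'q_hat - width, inf)``; ``less`` mirrors to
    ``(-inf, h'q_hat + width]``.
    """
    estimates = np.asarray(estimates, dtype=float)
    width = np.asarray(scale) * np.asarray(crit_values) / np.sqrt(n)
    if alternative == "two_sided":
        return estimates - width, estimates + width
    if direction == "greater":
        return estimates - width, np.full_like(estimates, np.inf)
    return np.full_like(estimates, -np.inf), estimates + width


def adjusted_p_values(statistics, crit: CriticalValues, r: int):
    """Adjusted p-values matched to the critical-value construction.

    Returns ``(adjusted, raw)``.  Resampling p-values use the add-one
    estimator ``(1 + #{draw >= t}) / (B + 1)``; Bonferroni routes multiply the
    per-contrast p by ``r`` (clipped at 1); the asymptotic MCTP uses the plain
    Monte-Carlo proportion floored at ``1/M``.
    """
    t = np.abs(statistics) if crit.alternative == "two_sided" else np.asarray(statistics)
    if crit.method == "bonf-asymptotic":
        raw = stats.norm.sf(t)
        if crit.alternative == "two_sided":
            raw = 2.0 * raw
        return np.minimum(1.0, r * raw), np.minimum(1.0, raw)
    if crit.method == "bonf-permutation":
        b = crit.draws.shape[0]
        count = (crit.draws >= t[None, :]).sum(axis=0)
        raw = (1.0 + count) / (b + 1.0)
        return np.minimum(1.0, r * raw), raw
    if crit.method == "mctp-asymptotic":
        m = crit.draws.shape[0]
        p = np.maximum((crit.draws[:, None] >= t[None, :]).mean(axis=0), 1.0 / m)
        return p, p
    if crit.method == "mctp-bootstrap":
        b = crit.draws.shape[0]
        p = (1.0 + (crit.draws[:, None] >= t[None, :]).sum(axis=0)) / (b + 1.0)
        return p, p
    raise ValueError(f"unknown method {crit.method!r}")


def _compute_critical_values(gs, spec, family, method, alternative, alpha,
                             cov, cov_method, n_resamples, n_mc, seed,
                             cov_kwargs):
    if method == "bonf-asymptotic":
        return crit_bonf_asymptotic(alpha, family.r, alternative)
    if method == "bonf-permutation":
        return crit_bonf_permutation(
            gs, spec, family, alpha=alpha, n_perm=n_resamples, seed=seed,
            cov_method=cov_method, alternative=alternative, cov_kwargs=cov_kwargs,
        )
    if method == "mctp-asymptotic":
        return crit_mctp_asymptotic(
            family, cov, alpha=alpha, alternative=alternative,
            n_draws=n_mc, seed=seed,
        )
    if method == "mctp-bootstrap":
        return crit_mctp_bootstrap(
            gs, spec, family, alpha=alpha, n_boot=n_resamples, seed=seed,
            cov_method=cov_method, alternative=alternative, cov_kwargs=cov_kwargs,
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _spawn_seeds(seed, n):
    if seed is None:
        return [None] * n
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def run_multiple_test(gs: GroupedSample, spec: QuantileSpec,
                      family: ContrastFamily, hyp: HypothesisSpec,
                      method: str = "mctp-asymptotic",
                      cov_method: str = "kernel",
                      n_resamples: int = None, n_mc: int = DEFAULT_N_MC,
                      seed=None, cov_kwargs: dict = None) -> TestResult:
    """Run one complete simultaneous test and return the full result."""
    if hyp.alternative == "equivalence":
        return run_equivalence_tost(
            gs, spec, family, hyp.delta, alpha=hyp.alpha, method=method,
            cov_method=cov_method, n_resamples=n_resamples, n_mc=n_mc,
            seed=seed, cov_kwargs=cov_kwargs,
        )
    if n_resamples is None:
        n_resamples = DEFAULT_N_RESAMPLES
    cov_kwargs = dict(cov_kwargs or {})
    cov_seed, crit_seed = _spawn_seeds(seed, 2)

    eps = np.broadcast_to(np.asarray(hyp.margins, dtype=float), (family.r,)).copy()
    work = family.with_margins(eps)
    flipped = hyp.alternative == "noninferiority" and hyp.direction == "less"
    if flipped:
        work = work.negated()

    if cov_method == "bootstrap" and "seed" not in cov_kwargs:
        cov_kwargs["seed"] = cov_seed
    cov = estimate_covariance(gs, spec, cov_method, **cov_kwargs)
    crit_cov_kwargs = {k: v for k, v in cov_kwargs.items() if k != "seed"}

    bundle: StatisticsBundle = studentized_contrasts(gs, spec, work, cov)
    crit = _compute_critical_values(
        gs, spec, work, method, hyp.alternative, hyp.alpha, cov, cov_method,
        n_resamples, n_mc, crit_seed, crit_cov_kwargs,
    )

    t_work = bundle.statistics
    if hyp.alternative == "two_sided":
        reject = np.abs(t_work) > crit.values
    else:
        reject = t_work > crit.values
    padj, praw = adjusted_p_values(t_work, crit, family.r)

    lo_w, hi_w = simultaneous_cis(work.matrix @ bundle.quantiles.values,
                                  bundle.scale, gs.n, crit.values,
                                  hyp.alternative, "greater")
    if flipped:
        estimates = -(work.matrix @ bundle.quantiles.values)
        statistics = -t_work
        ci_lower, ci_upper = -hi_w, -lo_w
    else:
        estimates = work.matrix @ bundle.quantiles.values
        statistics = t_work
        ci_lower, ci_upper = lo_w, hi_w

    return TestResult(
        row_labels=list(family.row_labels),
        estimates=estimates,
        margins=eps,
        statistics=statistics,
        critical_values=crit.values.copy(),
        reject=reject,
        pvalues=padj,
        pvalues_raw=praw,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        reject_global=bool(np.any(reject)),
        method=method,
        cov_method=cov_method,
        alternative=hyp.alternative,
        direction=hyp.direction,
        alpha=hyp.alpha,
        n=gs.n,
        sizes=gs.sizes,
        seed=seed,
        n_resamples=crit.n_draws,
        correlation=bundle.correlation,
        diagnostics=crit.diagnostics,
    )


def run_equivalence_tost(gs: GroupedSample, spec: QuantileSpec,
                         family: ContrastFamily, delta, alpha: float = 0.05,
                         method: str = "mctp-asymptotic",
                         cov_method: str = "kernel", n_resamples: int = None,
                         n_mc: int = DEFAULT_N_MC, seed=None,
                         cov_kwargs: dict = None,
                         one_sided_level: float = None) -> TestResult:
    """Two one-sided tests for ``H0_l: |h_l'q| >= delta_l``.

    Equivalence for contrast ``l`` is concluded iff both the test of
    ``h_l'q > -delta_l`` and the test of ``h_l'q < delta_l`` reject, each run
    at level ``alpha/2`` (configurable via ``one_sided_level``).
    """
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (family.r,)).copy()
    if np.any(delta <= 0):
        raise ValueError("equivalence half-widths delta must be positive")
    level = alpha / 2.0 if one_sided_level is None else one_sided_level
    s1, s2 = _spawn_seeds(seed, 2)
    lower = run_multiple_test(
        gs, spec, family,
        HypothesisSpec("noninferiority", "greater", margins=-delta, alpha=level),
        method=method, cov_method=cov_method, n_resamples=n_resamples,
        n_mc=n_mc, seed=s1, cov_kwargs=cov_kwargs,
    )
    upper = run_multiple_test(
        gs, spec, family,
        HypothesisSpec("noninferiority", "less", margins=delta, alpha=level),
        method=method, cov_method=cov_method, n_resamples=n_resamples,
        n_mc=n_mc, seed=s2, cov_kwargs=cov_kwargs,
    )
    reject = lower.reject & upper.reject
    pvalues = np.maximum(lower.pvalues, upper.pvalues)
    return TestResult(
        row_labels=list(family.row_labels),
        estimates=lower.estimates,
        margins=delta,
        statistics=np.where(np.abs(lower.statistics) < np.abs(upper.statistics),
                            lower.statistics, upper.statistics),
        critical_values=np.maximum(lower.critical_values, upper.critical_values),
        reject=reject,
        pvalues=pvalues,
        pvalues_raw=np.maximum(lower.pvalues_raw, upper.pvalues_raw),
        ci_lower=lower.ci_lower,
        ci_upper=upper.ci_upper,
        reject_global=bool(np.any(reject)),
        method=method,
        cov_method=cov_method,
        alternative="equivalence",
        direction="greater",
        alpha=alpha,
        n=gs.n,
        sizes=gs.sizes,
        seed=seed,
        n_resamples=max(lower.n_resamples, upper.n_resamples),
        correlation=lower.correlation,
        extra={"lower": lower, "upper": upper, "one_sided_level": level},
    )
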