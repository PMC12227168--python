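"""Synthetic data generation and the FWER / power simulation engine.

Data are drawn from the location-scale model

    X_is = sigma_i * (eta_is - m_i) + mu_i,

where the eta_is are i.i.d. from one of five reference distributions --
N(0,1), LN(0,1), chi-square(3), t(2), t(3) -- and ``m_i`` is the median of
that distribution (computed from the inverse CDF, not estimated), so that the
population median of group ``i`` is exactly ``mu_i``.  This family covers
symmetric light tails, strong right skew, and heavy tails with (t2) and
without (t3) infinite variance.

Two scenario grids are provided: a small-sample grid with ``k = 4`` groups
crossing sample-size/variance pairings, the five distributions, three contrast
families and two hypothesis types (120 null cells), and a larger grid modelled
on a 17-group observational design with strongly unbalanced group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import make_dunnett, make_grandmean, make_simultaneous_med_iqr, make_tukey, QuantileSpec
from .estimation import EstimationError, GroupedSample
from .inference import HypothesisSpec, run_multiple_test

__all__ = [
    "DISTRIBUTIONS",
    "ScenarioConfig",
    "MethodSummary",
    "SimulationSummary",
    "generate_sample",
    "true_quantile_vector",
    "small_sample_grid",
    "data_example_grid",
    "run_scenario",
    "summaries_to_frame",
    "synthetic_many_group_fixture",
    "DATA_EXAMPLE_SIZES",
]

DISTRIBUTIONS = {
    "normal": stats.norm(),
    "lognormal": stats.lognorm(1.0),   # LN(0, 1)
    "chisq3": stats.chi2(3),
    "t2": stats.t(2),
    "t3": stats.t(3),
}

_MEDIANS = {name: float(d.ppf(0.5)) for name, d in DISTRIBUTIONS.items()}

#: group sizes of the 17-group observational design (total 4616)
DATA_EXAMPLE_SIZES = (59, 175, 98, 78, 280, 176, 351, 128, 368, 403, 240,
                      376, 278, 549, 428, 379, 250)


@dataclass
class ScenarioConfig:
    name: str
    distribution: str
    sizes: tuple
    scales: tuple
    shifts: tuple
    contrasts: str = "tukey"          # dunnett | tukey | grandmean
    base: int = 1
    alternative: str = "two_sided"    # two_sided | noninferiority
    margins: float = 0.0
    alpha: float = 0.05
    nsim: int = 5000
    n_resamples: int = 2000
    cov_method: str = "kernel"
    probabilities: tuple = (0.5,)
    med_iqr: bool = False

    def __post_init__(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"choose from {tuple(DISTRIBUTIONS)}"
            )
        if len(self.scales) != len(self.sizes) or len(self.shifts) != len(self.sizes):
            raise ValueError("sizes, scales and shifts must have equal length")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.nsim < 1:
            raise ValueError("nsim must be at least 1")

    @property
    def k(self) -> int:
        return len(self.sizes)

    def family(self, labels=None):
        if self.contrasts == "dunnett":
            fam = make_dunnett(self.k, base=self.base, labels=labels)
        elif self.contrasts == "tukey":
            fam = make_tukey(self.k, labels=labels)
        elif self.contrasts == "grandmean":
            fam = make_grandmean(self.k, labels=labels)
        else:
            raise ValueError(f"unknown contrast tag {self.contrasts!r}")
        if self.med_iqr:
            fam = make_simultaneous_med_iqr(fam)
        return fam

    def spec(self) -> QuantileSpec:
        if self.med_iqr:
            return QuantileSpec((0.25, 0.5, 0.75))
        return QuantileSpec(tuple(self.probabilities))


def generate_sample(cfg: ScenarioConfig, seed=None) -> GroupedSample:
    """Draw one data set from the location-scale model of the scenario."""
    rng = np.random.default_rng(seed)
    dist = DISTRIBUTIONS[cfg.distribution]
    med = _MEDIANS[cfg.distribution]
    groups = []
    for ni, sig, mu in zip(cfg.sizes, cfg.scales, cfg.shifts):
        eta = dist.rvs(size=ni, random_state=rng)
        groups.append(sig * (eta - med) + mu)
    return GroupedSample(groups)


def true_quantile_vector(cfg: ScenarioConfig, spec: QuantileSpec) -> np.ndarray:
    """Population quantiles ``q_ij = sigma_i*(F^-1(p_j) - m_i) + mu_i``, group-major."""
    dist = DISTRIBUTIONS[cfg.distribution]
    med = _MEDIANS[cfg.distribution]
    qd = np.array([float(dist.ppf(p)) for p in spec.probabilities])
    out = np.empty(cfg.k * spec.m)
    for i, (sig, mu) in enumerate(zip(cfg.scales, cfg.shifts)):
        out[i * spec.m:(i + 1) * spec.m] = sig * (qd - med) + mu
    return out


# ---------------------------------------------------------------------------
# scenario grids
# ---------------------------------------------------------------------------

_SMALL_N = {"n1": (15, 15, 15, 15), "n2": (10, 10, 20, 20)}
_SMALL_SIGMA = {"s1": (1.0, 1.0, 1.0, 1.0),
                "s2": (1.0, 1.25, 1.5, 1.75),
                "s3": (1.75, 1.5, 1.25, 1.0)}
#: (size, scale) pairings: balanced homo/heteroskedastic plus unbalanced with
#: positive (s2) and negative (s3) pairing
DEFAULT_PAIRINGS = (("n1", "s1"), ("n1", "s2"), ("n2", "s2"), ("n2", "s3"))

_SMALL_FAMILIES = ("dunnett", "tukey", "grandmean")
_HYPOTHESES = ("two_sided", "noninferiority")


def small_sample_grid(kind: str = "null", nsim: int = 5000,
                      n_resamples: int = 2000, alpha: float = 0.05,
                      cov_method: str = "kernel", pairings=DEFAULT_PAIRINGS,
                      deltas=(0.5, 1.0, 1.5)) -> list:
    """The k=4 median-contrast scenario grid (120 null cells by default).

    ``kind='null'`` sets all shifts to zero; ``kind='power'`` adds each shift
    delta to the fourth group, tripling the cell count.
    """
    if kind not in ("null", "power"):
        raise ValueError("kind must be 'null' or 'power'")
    shift_sets = [("mu0", (0.0, 0.0, 0.0, 0.0))] if kind == "null" else \
        [(f"d{d:g}", (0.0, 0.0, 0.0, d)) for d in deltas]
    cells = []
    for ntag, stag in pairings:
        for dist in DISTRIBUTIONS:
            for fam in _SMALL_FAMILIES:
                for hyp in _HYPOTHESES:
                    for mtag, shifts in shift_sets:
                        cells.append(ScenarioConfig(
                            name=f"{ntag}-{stag}-{dist}-{fam}-{hyp}-{mtag}",
                            distribution=dist,
                            sizes=_SMALL_N[ntag],
                            scales=_SMALL_SIGMA[stag],
                            shifts=shifts,
                            contrasts=fam,
                            base=1,
                            alternative=hyp,
                            alpha=alpha,
                            nsim=nsim,
                            n_resamples=n_resamples,
                            cov_method=cov_method,
                        ))
    return cells


def data_example_grid(scales, shifts=None, nsim: int = 5000,
                      n_resamples: int = 2000, alpha: float = 0.05,
                      cov_method: str = "kernel") -> list:
    """The 17-group grid: Dunnett base 17, r = 16, t2 excluded.

    ``scales`` (length 17) plays the role of the data-derived group scales;
    ``shifts`` defaults to the global null (all zero).
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) != 17:
        raise ValueError("scales must have length 17")
    if shifts is None:
        shifts = (0.0,) * 17
    shifts = tuple(float(s) for s in shifts)
    if len(shifts) != 17:
        raise ValueError("shifts must have length 17")
    cells = []
    for dist in ("normal", "lognormal", "chisq3", "t3"):  # t2: no variance
        for hyp in _HYPOTHESES:
            cells.append(ScenarioConfig(
                name=f"example-{dist}-{hyp}",
                distribution=dist,
                sizes=DATA_EXAMPLE_SIZES,
                scales=scales,
                shifts=shifts,
                contrasts="dunnett",
                base=17,
                alternative=hyp,
                alpha=alpha,
                nsim=nsim,
                n_resamples=n_resamples,
                cov_method=cov_method,
            ))
    return cells


# ---------------------------------------------------------------------------
# scenario engine
# ---------------------------------------------------------------------------

@dataclass
class MethodSummary:
    method: str
    n_effective: int
    n_failed: int
    any_null_rejection_rate: float = None   # empirical FWER (true nulls present)
    global_rejection_rate: float = None
    local_rates: np.ndarray = None

    @property
    def fwer(self):
        return self.any_null_rejection_rate

    def standard_error(self, rate) -> float:
        if rate is None or self.n_effective == 0:
            return float("nan")
        return float(np.sqrt(rate * (1.0 - rate) / self.n_effective))


@dataclass
class SimulationSummary:
    config: ScenarioConfig
    methods: dict = field(default_factory=dict)  # method name -> MethodSummary
    null_contrasts: np.ndarray = None            # bool mask of true local nulls
    seed: object = None


def _null_mask(cfg: ScenarioConfig, family) -> np.ndarray:
    q_true = true_quantile_vector(cfg, cfg.spec())
    effects = family.matrix @ q_true
    eps = np.broadcast_to(np.asarray(cfg.margins, dtype=float), (family.r,))
    if cfg.alternative == "two_sided":
        return np.abs(effects - eps) < 1e-12
    return effects <= eps + 1e-12


def run_scenario(cfg: ScenarioConfig, methods, seed=None, n_mc: int = 20_000,
                 max_failure_fraction: float = 0.01) -> SimulationSummary:
    """Estimate FWER / power for one scenario cell and a list of methods.

    Each replicate gets an independent random substream derived from the
    master seed, so results do not depend on evaluation order.  Replicates in
    which an estimator degenerates are dropped per method and counted; the
    scenario aborts if more than ``max_failure_fraction`` of them fail.
    """
    if isinstance(methods, str):
        methods = [methods]
    family = cfg.family()
    nulls = _null_mask(cfg, family)
    hyp = HypothesisSpec(alternative=cfg.alternative, margins=cfg.margins,
                         alpha=cfg.alpha)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.nsim)
    rejected = {m: [] for m in methods}
    global_rej = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    for child in children:
        gen_seed, test_seed = child.spawn(2)
        gs = generate_sample(cfg, seed=np.random.default_rng(gen_seed))
        tseed = int(test_seed.generate_state(1)[0] % (2**31))
        for method in methods:
            try:
                res = run_multiple_test(
                    gs, cfg.spec(), family, hyp, method=method,
                    cov_method=cfg.cov_method, n_resamples=cfg.n_resamples,
                    n_mc=n_mc, seed=tseed,
                )
            except EstimationError:
                failures[method] += 1
                if failures[method] > max(1, max_failure_fraction * cfg.nsim):
                    raise
                continue
            rejected[method].append(res.reject)
            global_rej[method].append(res.reject_global)
    summary = SimulationSummary(config=cfg, null_contrasts=nulls, seed=seed)
    for method in methods:
        rej = np.array(rejected[method], dtype=bool)
        n_eff = rej.shape[0]
        ms = MethodSummary(method=method, n_effective=n_eff,
                           n_failed=failures[method])
        if n_eff:
            ms.local_rates = rej.mean(axis=0)
            ms.global_rejection_rate = float(np.mean(global_rej[method]))
            if nulls.any():
                ms.any_null_rejection_rate = float(rej[:, nulls].any(axis=1).mean())
        summary.methods[method] = ms
    return summary


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Flatten scenario summaries into one row per (cell, method)."""
    rows = []
    for s in summaries:
        for m, ms in s.methods.items():
            fwer = ms.any_null_rejection_rate
            rows.append({
                "scenario": s.config.name,
                "distribution": s.config.distribution,
                "contrasts": s.config.contrasts,
                "alternative": s.config.alternative,
                "cov_method": s.config.cov_method,
                "method": m,
                "nsim": ms.n_effective,
                "n_failed": ms.n_failed,
                "fwer": fwer,
                "fwer_se": ms.standard_error(fwer),
                "global_power": ms.global_rejection_rate,
            })
    return pd.DataFrame(rows)


def synthetic_many_group_fixture(seed=None, sizes=DATA_EXAMPLE_SIZES) -> pd.DataFrame:
    """A synthetic 17-group long-format data set for documentation and tests.

    Groups are skewed, heteroskedastic and heavy-tailed (rotating through
    LN(0,1), chi-square(3) and t(3) shapes with varying scale and location on
    a day-of-year-like axis).  Purely synthetic: it mimics the *structure* of
    a multi-year observational phenology data set, not any real data.
    """
    rng = np.random.default_rng(seed)
    shapes = ("lognormal", "chisq3", "t3")
    rows = []
    for i, ni in enumerate(sizes):
        dist_name = shapes[i % len(shapes)]
        dist = DISTRIBUTIONS[dist_name]
        med = _MEDIANS[dist_name]
        sigma = 3.0 + 4.0 * ((i * 7) % 5) / 4.0
        mu = 120.0 + 10.0 * np.sin(0.8 * i) + (3.0 if i % 4 == 0 else 0.0)
        eta = dist.rvs(size=ni, random_state=rng)
        vals = sigma * (eta - med) + mu
        year = 2006 + i
        rows.append(pd.DataFrame({"group": str(year), "value": vals}))
    return pd.concat(rows, ignore_index=True)
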