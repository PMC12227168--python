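"""Model/Results facade for simultaneous quantile contrast testing.

``QuantileContrastTest`` is constructed from grouped data plus a contrast
specification; ``fit`` runs one of the four procedures and returns a
``QuantileContrastResults`` carrying estimates, critical values, adjusted
p-values, simultaneous confidence bounds, and a printable ``summary()``.

Example
-------
>>> import numpy as np
>>> rng = np.random.default_rng(0)
>>> samples = [rng.normal(mu, 1, 40) for mu in (0, 0, 1.5)]
>>> model = QuantileContrastTest(samples, contrasts="tukey")
>>> res = model.fit(method="mctp-asymptotic", seed=1)
>>> bool(res.reject_global)
True
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import (
    ContrastFamily,
    MED_IQR,
    QuantileSpec,
    make_dunnett,
    make_grandmean,
    make_simultaneous_med_iqr,
    make_tukey,
    validate_contrast_family,
)
from .estimation import GroupedSample
from .inference import HypothesisSpec, TestResult, run_equivalence_tost, run_multiple_test

__all__ = ["QuantileContrastTest", "QuantileContrastResults"]


def _build_family(contrasts, k, labels, base, med_iqr):
    if isinstance(contrasts, ContrastFamily):
        fam = contrasts
    elif contrasts == "dunnett":
        fam = make_dunnett(k, base=base, labels=labels)
    elif contrasts == "tukey":
        fam = make_tukey(k, labels=labels)
    elif contrasts == "grandmean":
        fam = make_grandmean(k, labels=labels)
    else:
        raise ValueError(
            f"contrasts must be a ContrastFamily or one of "
            f"'dunnett', 'tukey', 'grandmean'; got {contrasts!r}"
        )
    if med_iqr:
        if fam.m != 1:
            raise ValueError("med_iqr expansion needs an m=1 base family")
        fam = make_simultaneous_med_iqr(fam)
    return fam


class QuantileContrastTest:
    """Simultaneous tests for linear contrasts of group quantiles.

    Parameters
    ----------
    samples : sequence of array-like
        One vector of observations per group.
    group_names : sequence of str, optional
    probabilities : tuple of float
        The quantile probabilities of interest (default: the median).
    contrasts : str or ContrastFamily
        ``'dunnett'`` (many-to-one), ``'tukey'`` (all pairs), ``'grandmean'``,
        or an explicit family.
    base : int
        1-indexed base group for Dunnett contrasts.
    med_iqr : bool
        Expand the family to joint median + IQR contrasts over
        ``p = (0.25, 0.5, 0.75)``.
    """

    def __init__(self, samples, group_names=None, *, probabilities=(0.5,),
                 contrasts="tukey", base=1, med_iqr=False):
        self.data = GroupedSample(list(samples), labels=group_names)
        if self.data.k < 2:
            raise ValueError("inference requires at least two groups")
        self.spec = MED_IQR if med_iqr else QuantileSpec(tuple(probabilities))
        self.family = _build_family(contrasts, self.data.k, self.data.labels,
                                    base, med_iqr)
        report = validate_contrast_family(self.family, self.data.k, self.spec)
        if not report.ok:
            raise ValueError(f"invalid contrast family: {report.messages}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str, value_col: str,
                       order=None, **kwargs) -> "QuantileContrastTest":
        """Build from a long-format table (one row per observation)."""
        vals = pd.to_numeric(df[value_col], errors="coerce")
        keep = vals.notna()
        groups = df.loc[keep, group_col]
        vals = vals[keep]
        names = list(pd.unique(groups)) if order is None else list(order)
        samples = [vals[groups == g].to_numpy(dtype=float) for g in names]
        return cls(samples, group_names=[str(g) for g in names], **kwargs)

    def fit(self, method: str = "mctp-asymptotic", cov: str = "kernel",
            alternative: str = "two_sided", direction: str = "greater",
            margins=0.0, alpha: float = 0.05, n_resamples: int = None,
            n_mc: int = 100_000, seed=None, cov_kwargs=None) -> "QuantileContrastResults":
        hyp = HypothesisSpec(alternative=alternative, direction=direction,
                             margins=margins, alpha=alpha)
        result = run_multiple_test(
            self.data, self.spec, self.family, hyp, method=method,
            cov_method=cov, n_resamples=n_resamples, n_mc=n_mc, seed=seed,
            cov_kwargs=cov_kwargs,
        )
        return QuantileContrastResults(self, result)

    def fit_equivalence(self, delta, alpha: float = 0.05,
                        method: str = "mctp-asymptotic", cov: str = "kernel",
                        n_resamples: int = None, n_mc: int = 100_000,
                        seed=None, cov_kwargs=None,
                        one_sided_level=None) -> "QuantileContrastResults":
        result = run_equivalence_tost(
            self.data, self.spec, self.family, delta, alpha=alpha,
            method=method, cov_method=cov, n_resamples=n_resamples,
            n_mc=n_mc, seed=seed, cov_kwargs=cov_kwargs,
            one_sided_level=one_sided_level,
        )
        return QuantileContrastResults(self, result)


class QuantileContrastResults:
    """Fitted results wrapper with a statsmodels-flavoured surface."""

    def __init__(self, model: QuantileContrastTest, result: TestResult):
        self.model = model
        self._result = result

    # plain attribute pass-through for the common fields
    def __getattr__(self, name):
        try:
            return getattr(self._result, name)
        except AttributeError:  # pragma: no cover
            raise AttributeError(name) from None

    @property
    def result(self) -> TestResult:
        return self._result

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lower": self._result.ci_lower, "upper": self._result.ci_upper},
            index=self._result.row_labels,
        )

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def summary(self) -> str:
        r = self._result
        alt = {"two_sided": "two-sided", "noninferiority":
               f"noninferiority ({r.direction})", "equivalence": "equivalence (TOST)"}
        head = [
            "Simultaneous Quantile Contrast Test",
            "=" * 74,
            f"Hypotheses:     {alt[r.alternative]}   alpha = {r.alpha:g}",
            f"Method:         {r.method}   covariance: {r.cov_method}",
            f"Groups:         k = {len(r.sizes)}   n = {r.n}   "
            f"probabilities = {self.model.spec.probabilities}",
        ]
        if r.n_resamples:
            head.append(f"Resampling:     {r.n_resamples} draws   seed = {r.seed}")
        body = r.to_frame().copy()
        for col in ("estimate", "statistic", "critical_value"):
            body[col] = body[col].map(lambda v: f"{v:.4f}")
        body["p_adjusted"] = body["p_adjusted"].map(lambda v: f"{v:.4f}")
        body["ci_lower"] = body["ci_lower"].map(lambda v: f"{v:.4f}" if np.isfinite(v) else "-inf")
        body["ci_upper"] = body["ci_upper"].map(lambda v: f"{v:.4f}" if np.isfinite(v) else "inf")
        tail = [
            "-" * 74,
            f"Global hypothesis {'REJECTED' if r.reject_global else 'not rejected'} "
            f"({int(r.reject.sum())} of {len(r.reject)} local rejections)",
        ]
        return "\n".join(head) + "\n" + body.to_string(index=False) + "\n" + "\n".join(tail)

    def __repr__(self) -> str:  # pragma: no cover
        r = self._result
        return (f"<QuantileContrastResults method={r.method} "
                f"reject_global={r.reject_global}>")
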