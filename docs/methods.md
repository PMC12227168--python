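# Methods

## Model and estimands

We observe `k ≥ 2` mutually independent samples `X_i1, …, X_in_i ~ F_i` and
target the quantiles `q_ij = F_i^{-1}(p_j) = inf{u : F_i(u) ≥ p_j}` for
probabilities `0 < p_1 < … < p_m < 1`. All inference assumes `F_i` is
continuously differentiable at each target quantile with positive density
`f_i(q_ij) > 0`, and that group shares stabilize (`n_i/n → κ_i > 0`). Under
this assumption `√n(q̂ − q)` is asymptotically normal with block-diagonal
covariance

    Σ^(i)_ab = κ_i^{-1} (min(p_a, p_b) − p_a p_b) / (f_i(q_ia) f_i(q_ib)).

Heavy ties in the data contradict the positive-density assumption; the
covariance estimators therefore raise errors on degenerate spacings instead
of silently flooring density values.

The empirical quantile is the left-continuous inverse of the empirical CDF,
i.e. the `⌈n_i p⌉`-th order statistic — deliberately *not* an interpolating
quantile, so the estimator matches the estimand definition exactly. Contrast
families are `r × km` matrices in group-major layout (`(i−1)m + j`); every
builder output satisfies the per-probability zero-sum contrast property and
is validated on model construction.

## Covariance estimators

The densities `f_i(q_ij)` are the only unknown in `Σ`; three plug-ins are
provided, selected by `cov ∈ {kernel, bootstrap, interval}`:

* **kernel** — Gaussian kernel density estimate evaluated at `q̂_ij` with
  Silverman rule-of-thumb bandwidth `0.9 n_i^{-1/5} min(SD, IQR/1.34)`
  (the `bw.nrd0` variant; interpolating quartiles for the IQR). Fallbacks for
  degenerate spreads: zero IQR → SD; constant sample → bandwidth scale 1 with
  a warning.
* **bootstrap** — each group is resampled with replacement `B_cov` times
  (default 2000) and `Σ̂^(i) = n · Cov_boot(q̂*^(i))`. A constant resampled
  quantile is an error (ties indicator).
* **interval** — around the target rank a window of half-width
  `λ = z_{1−γ/2} √(n_i p (1−p))` ranks (default `γ = 0.05`) is bracketed by
  order statistics `X_(L), X_(U)` with `L = max(⌈n_i p − λ⌉, 1)`,
  `U = min(⌈n_i p + λ⌉, n_i)`; the reciprocal density is estimated by the
  spacing over the probability width it covers,
  `1/f̂ = n_i (X_(U) − X_(L)) / (2λ)`. Tied or non-bracketing order statistics
  are errors.

All three are consistent; their single-sample dispersion is large by nature
(quantile-variance estimation converges at the `n^{-1/4}` rate), which is why
the parameter-recovery tests average over independent samples rather than
judging single draws.

## Test statistics and critical values

Each contrast is studentized: `T_n(h_ℓ, ε_ℓ) = √n(h_ℓ'q̂ − ε_ℓ)/√(h_ℓ'Σ̂h_ℓ)`.
Jointly the statistics converge to `N(0, R)` with `R = DHΣH'D`,
`D = diag((h_ℓ'Σh_ℓ)^{-1/2})`; each margin is standard normal. Four critical
value constructions are implemented:

1. **Bonferroni asymptotic** — `z_{1−α/(2r)}` (two-sided) or `z_{1−α/r}`
   (one-sided) for every contrast.
2. **Bonferroni permutation** — samples of the original sizes are drawn
   without replacement from the pooled data; quantiles *and* the covariance
   estimate are recomputed on every permuted data set (studentized
   permutation), giving `T^π_ℓ = √n h_ℓ'q̂^π / √(h_ℓ'Σ̂^π h_ℓ)`. Per contrast
   the critical value is the `⌈B(1−α/r)⌉`-th order statistic of the `|T^π_ℓ|`
   (two-sided) or `T^π_ℓ` (one-sided) draws. The studentization makes the
   procedure asymptotically valid without exchangeability; under
   exchangeability it is finitely exact. The two-sided quantile is taken from
   the absolute-value permutation distribution, which by symmetry matches the
   `z_{1−α/(2r)}` limit.
3. **Asymptotic max-t MCTP** — one common critical value, the Monte-Carlo
   `(1−α)`-quantile of `max_ℓ |Y_ℓ|` (or `max_ℓ Y_ℓ`) over `M = 10^5` draws
   `Y = D̂ H A Z` with `A A' = Σ̂`. Sampling through a factor of `Σ̂` rather
   than `R̂` keeps rank-deficient families (Tukey) well-defined without
   regularization; the factor is a Cholesky with an eigenvalue-clipping
   fallback for semidefinite input.
4. **Groupwise bootstrap MCTP** — with-replacement resampling per group;
   counterparts `T*_ℓ = √n h_ℓ'(q̂* − q̂)/√(h_ℓ'Σ̂*h_ℓ)` with the covariance
   recomputed on each bootstrap sample; critical value from the max (or
   max-abs) draws. Choosing the bootstrap covariance here nests an inner
   resampling loop inside each outer replicate.

Resampling conventions, shared by all engines: empirical quantiles of
resampling distributions use the `⌈Bβ⌉`-th order statistic; degenerate
replicates (non-positive studentizer, tied interval order statistics) are
dropped and counted, and more than 10% dropped is an error; all randomness
flows from one user seed through `numpy.random.SeedSequence` substreams, so
results are independent of evaluation order. Defaults are `B = 1999` for
single-data-set analyses and `B = 2000` inside the simulation engine.

P-values match the critical-value constructions: resampling routes use the
add-one estimator `(1 + #{draw ≥ t})/(B + 1)` (Bonferroni routes multiply by
`r`, clipped at 1); the asymptotic max-t route uses the Monte-Carlo
proportion floored at `1/M`. Rejection at level α and "margin outside the
simultaneous interval" are algebraically the same event; resampling p-values
agree with decisions up to the `1/(B+1)` granularity at the boundary.

One-sided direction handling: a `direction="less"` family is converted to
the canonical "greater" form by negating rows and margins, and estimates and
confidence bounds are mirrored back, which yields `(−∞, upper]` intervals for
hypotheses of the form "base minus group ≥ margin". Equivalence uses two
one-sided tests at level `α/2` each (configurable); equivalence for a
contrast is concluded only if both reject, and the reported interval is the
intersection of the two one-sided bounds.

## Synthetic data generator

`simulation.generate_sample` draws from the location-scale model
`X_is = σ_i(η_is − m_i) + μ_i` with `η_is` i.i.d. from one of five reference
shapes — N(0,1), LN(0,1), χ²₃, t₂, t₃ — and `m_i` the median of that shape,
computed from the inverse CDF (LN: 1, χ²₃: ≈ 2.36597, t: 0), so the
population median of group `i` is exactly `μ_i`. The family covers symmetric
light tails, strong right skew, and heavy tails with and without finite
variance. What it does **not** emulate: dependence between observations,
measurement rounding/ties, contamination, or group-specific shape changes —
so passing simulations demonstrate calibration under clean independent
location-scale alternatives, not robustness to tied or dependent real data.

Two scenario grids mirror a two-part design:

* **small-sample grid** — `k = 4`, medians (`p = 0.5`), four size/scale
  pairings {balanced homoskedastic, balanced heteroskedastic, unbalanced with
  positive pairing, unbalanced with negative pairing} × five distributions ×
  three contrast families (Dunnett base 1, Tukey, grand-mean) × two
  hypothesis types = 120 null cells; power cells add a shift
  `δ ∈ {0.5, 1, 1.5}` to the fourth group. The exact size/scale crossing is a
  reconstruction reproducing the 120-cell count; the grid builder accepts any
  explicit pairing list. Reference Monte-Carlo sizes are `Nsim = 5000`,
  `B = 2000`, `α = 0.05`.
* **17-group grid** — the strongly unbalanced size vector (59, 175, …, 250)
  totalling 4616, Dunnett contrasts with base 17 (`r = 16`), user-supplied
  scales (data-derived scales are external inputs), four distributions (t₂
  excluded because its variance does not exist, so scales cannot be matched
  to empirical variances).

The engine `run_scenario` spawns one substream per replicate, records local
and global rejections per method, reports the empirical FWER (share of
replicates with ≥ 1 true-null rejection) with binomial standard errors and
global/local power, and aborts if more than 1% of replicates fail.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run a scaled version of the error
study: 1000 simulated data sets with 500 permutations each per cell (the
package's default trade-off between Monte-Carlo resolution and turnaround on
a single CPU). At this size the binomial 95% half-width around a 5% rate is
±0.0135, and acceptance regions are the 5000-run calibration band widened by
exactly that noise. The permutation-exactness check uses 2000 replications at
`B = 499`, where the one-sided rejection rule `T > T^π_(⌈0.95·B⌉)` attains the
nominal 5% exactly. Estimator parameter-recovery averages ten samples of
20,000 observations per distribution.

## Numerical choices and degenerate inputs

* Order-statistic indices guard against floating-point rounding with a 1e-9
  epsilon inside the ceiling.
* Contrast validation uses an absolute zero-sum tolerance of 1e-10; estimated
  correlation matrices get an exact unit diagonal by construction and are
  checked PSD to 1e-8.
* Degenerate studentizers raise errors naming the offending contrast; the
  covariance factorization raises if `Σ̂` is indefinite beyond tolerance.
* Batch (resampling) and scalar code paths implement identical formulas; the
  suite asserts bit-level agreement on shared inputs.

## Known limitations

* Quantile inference needs effectively continuous data; with many ties the
  estimators error out by design rather than returning unreliable output.
* The asymptotic routes are first-order; for very small groups (n_i ≲ 10)
  only the permutation route has finite-sample guarantees, and only under
  exchangeability.
* Stepwise multiplicity refinements (closed testing, Holm, Shaffer) are out
  of scope: the package only implements procedures that come with matching
  simultaneous confidence intervals.
* The bootstrap MCTP combined with the bootstrap covariance estimator is
  liberal in small samples (visible in the small-sample grid); the
  permutation route with any covariance estimator is the recommended default
  there.
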