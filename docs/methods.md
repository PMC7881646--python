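# Methods

## The problem

A metabolome-wide association study (MWAS) tests each of M metabolic
variates against an outcome Y, optionally adjusting for fixed-effect
covariates Z. With M in the hundreds to tens of thousands and the variates
highly collinear, a per-test significance threshold is needed that controls
the family-wise error rate (FWER) at level α without paying the full
Bonferroni price α/M. That threshold is the metabolome-wide significance
level (MWSL); the effective number of tests ENT = α/MWSL expresses it as
the size of an equivalent family of independent tests, and
R = 100·ENT/M summarises feature redundancy.

## Permutation estimate of the MWSL

1. Shuffle Y jointly with Z (one shared permutation of sample indices per
   replicate); features stay in place. This samples the global null while
   preserving the feature correlation structure and the Y–Z relationship.
2. Fit the M univariate models (one feature at a time, covariates always
   included) and store the feature-coefficient p-values.
3. Keep the minimum of the M p-values.
4. Repeat K times; the minima form the null vector q. K must be at least
   n/2; the default is max(10 000, n/2).
5. The MWSL is the ascending (αK)-th order statistic of q. Treating the
   true rank as Binomial(K, α) and applying the Normal approximation gives
   confidence limits at ranks (αK) ∓ (1−α)·sqrt(αK(1−α)). Real-valued
   ranks are rounded to the nearest integer and clamped to [1, K] — the
   rounding rule is our choice; the positions are stated in real numbers.
6. ENT = α/MWSL, computed from the unrounded MWSL.

### Association engines

The model family follows the outcome family: OLS (continuous), logistic
(binary), log-linear Poisson (count), Cox proportional hazards with the
Efron tie correction (survival). The default test is the two-sided Wald
test on the feature coefficient; a likelihood-ratio option and, for
continuous outcomes, a plain correlation test are provided.

A permutation run needs K × M fits, up to millions of small regressions,
so `mwsl._batched` fits all models of a replicate simultaneously: exact
Frisch–Waugh residualisation for OLS, batched Newton–Raphson IRLS for the
GLMs, and a batched partial-likelihood Newton for Cox. Two further
identities are exploited: (i) shuffling (Y, Z) jointly is equivalent to
inversely reordering the feature rows with (Y, Z) fixed, so whole
replicates are stacked as extra feature columns into one batched call;
(ii) for continuous outcomes without covariates the K×M p-value matrix
reduces to one correlation matmul. The batched fits are verified against
per-model statsmodels / lifelines fits in the test suite.

Failed fits — zero-variance features, collinearity with covariates,
separation in logistic models, non-convergence — are flagged missing (NaN)
and excluded from the minimum, never reported as p≈0: a single
miscalibrated test would otherwise drag the min-p null and bias the MWSL
downward. Replicates draw their shuffles from independent substreams of
one root seed (numpy `SeedSequence.spawn`), so results are bit-reproducible
and independent of evaluation order.

## Parametric approximation of the features

Raw metabolic intensities are typically right-skewed and heavy-tailed, and
skewness in both feature and outcome miscalibrates the univariate
p-values. The cure is to run the permutation on parametric surrogates that
keep the second-order structure but have well-behaved margins:

* **mvnormal** — centre the features, estimate the shrinkage covariance
  Σ\*, draw n rows from N(0, Σ\*).
* **mvlognormal** — shift every feature by |min|+1 (applied literally to
  each column regardless of sign, so a column with minimum 2 is shifted by
  3), take natural logs, model the logs as multivariate Normal with Σ\*
  estimated on the log scale, draw, exponentiate. Surrogates are strictly
  positive; an optional per-feature trigger (sample skewness > 1) restricts
  the log transform to skewed columns.

Σ\* follows the analytic linear-shrinkage recipe of Schäfer & Strimmer
(2005) with a diagonal unequal-variance target: sample correlations are
shrunk toward zero with intensity
λ\* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij², clipped to [0, 1], and the sample
variances are restored on the diagonal. Σ\* is positive definite and
well-conditioned even when M ≫ n, so its Cholesky factor always exists.
Fidelity is second-order only — no copula or higher-moment matching.
One surrogate matrix is drawn per run; the permutation then shuffles the
outcome against it.

## Closed-form effective number of tests (Meff)

Let λ₁ ≥ … ≥ λ_M be the eigenvalues of the feature correlation matrix
(negative eigenvalues within −10⁻⁸ are clipped to zero; the trace identity
Σλ = M is asserted before any estimator runs). Five estimators are
provided:

* **spectral balance** (the package's headline formula):
  Meff = ((Σ√λ_m)/ln λ₁)² / (Σλ_m/λ₁ + √λ₁), defined for λ₁ > 1.
  The logarithm is natural; the base is not fixed by the formula's
  derivation, and natural log is the convention used throughout.
* **Nyholt**: 1 + (M−1)(1 − Var(λ)/M). The sample variance (divisor M−1)
  is the default so the fully-correlated limit returns exactly 1; the
  population-variance convention (divisor M) is available and is the one
  that reproduces the reference value 34 for the strongest simulated
  correlation band (the sample-variance analytic value there is 33.0).
* **Li–Ji (as described)**: Σ min(λ, 1); the canonical floor/fraction form
  Σ [1(λ≥1) + (λ − ⌊λ⌋)] is available separately as `liji_canonical`.
* **Gao**: smallest k whose leading eigenvalues explain a fraction
  (default 0.995, configurable — there is no principled choice) of the
  total variance.
* **Galwey**: (Σ√λ)² / Σλ.

Rank-deficient spectra (n−1 < M) need no special handling: zero
eigenvalues contribute √0 = 0 and nothing is renormalised. Integer
reporting uses nearest-integer rounding; the raw value is always retained.

From a Meff value the threshold follows either by Bonferroni
(MWSL = α/Meff) or by the Beta model: under the null the minimum of Meff
effectively independent uniform p-values is Beta(1, Meff) (Beta(1,1) =
U(0,1) in the fully-correlated limit). `beta_approx_mwsl` either draws K
values from Beta(1, Meff) and reuses the permutation order-statistic
machinery (`sample`), or evaluates the quantile 1 − (1−α)^(1/Meff)
directly with confidence limits at the same order-statistic positions
(`analytic`).

## Synthetic data

`gen_correlated_features` draws Gaussian variates at a prescribed pairwise
correlation band. Nine presets span (0, 0.25) up to [0.95, 1). Two
structures: `equicorrelated` (constant correlation at the band midpoint,
generated via the closed-form Cholesky factor of compound symmetry —
the default, chosen because it is exactly reproducible and its Nyholt
values match the reference simulation table) and `random-within-band`
(off-diagonals uniform in the band, projected to the nearest
positive-definite correlation matrix by eigenvalue clipping at 10⁻⁸ and
renormalisation). A draw whose mean empirical off-diagonal correlation
misses the band is retried on a fresh substream (up to 5 times, then an
error).

`gen_outcome` covers the four families: Normal / Skew-Normal (shape 5 by
default) / Weibull (shape 0.8, strongly right-skewed) continuous outcomes,
Bernoulli, Poisson, and survival times by inverse transform from an
exponential baseline hazard (T = −log U / (h₀ e^lp)) with uniform
censoring whose upper bound is solved numerically so the expected censored
fraction hits the target (default 0.3). Outcomes are either independent of
the features (the null used in all type-I-error work), a weighted linear
combination of chosen features plus Gaussian noise, or coupled to the
features' common factor at a target correlation.

`pca_surrogate` provides a nonparametric alternative: split samples into
test/non-test, fit PCA on the non-test rows, project and reconstruct the
test rows from the top components — surrogate data that inherits the real
correlation structure without reusing any permutation machinery.

Simulation defaults mirror a serum NMR profiling setting (M = 650,
n = 3500, K = 5000); the test suite runs reduced sizes (M = 100, K = 1000
for the nine-band trend at n = 1000; K = K_eval = 2000 at n = 250 for the
FWER grid), chosen as the smallest sizes at which the Monte-Carlo error is
comfortably below the tolerances being asserted.

What the generators do **not** emulate: real NMR spectra's baseline
artefacts, peak shifts, block-correlation neighbourhoods, and non-Gaussian
margins beyond what the log-Normal surrogate captures. Passing tests
therefore certify the estimators' behaviour under well-specified
second-order structure, not under every pathology of real spectra — which
is precisely why the parametric approximation step exists for real data.

## FWER validation

Two evaluators are provided, probing two different nulls:

* `permutation_fwer` draws K_eval fresh, independent permutation
  replicates of the *same* outcome realisation — never the replicates
  that produced the threshold — and reports the fraction whose minimum
  p-value falls at or below it. The min-p permutation null is conditional
  on the observed outcome, so this is the error rate of the procedure as
  deployed on one study, and the check the 4 × 3 `validation_suite` grid
  (families × identity/mvnormal/mvlognormal) uses: in each cell the
  feature approximation is drawn once, the threshold is estimated on it,
  and the type-I error measured on the same features and outcome.
* `estimate_fwer` instead redraws the outcome itself per replicate,
  marginalising over realisations, with per-feature rejection rates as
  diagnostics.

The distinction matters: with well-behaved (Gaussian) features the min-p
law is nearly pivotal and the two agree, but with strongly skewed features
and discrete outcomes the conditional α-quantile varies between outcome
realisations, and only the conditional check reflects what the threshold
was built to control. Evaluating on the very replicates that produced the
threshold would return α identically, so the split (fresh substreams, or
fresh outcomes) is mandatory in both evaluators. Both report Wilson
binomial confidence intervals.

## Numerical choices and limitations

* IRLS clamps the linear predictor at ±30; Wald standard errors above 10³,
  coefficients at the clamp wall, and Newton steps that fail to settle
  below 10⁻⁵ are all treated as failed fits.
* The Cox partial likelihood is shift-invariant in the linear predictor;
  the batched engine recentres before exponentiating and damps Newton
  steps to ±5 per iteration.
* Quantile ranks and CI positions round to nearest and clamp to [1, K];
  with αK < 1 the run errors out rather than extrapolating.
* ENT can exceed M by sampling noise on genuinely independent features;
  the bounds α/M ≤ MWSL ≤ α hold up to Monte-Carlo error only.
* No step-down (per-feature adjusted) p-values are produced — the
  deliverable is the single study-wide threshold. No mixed-effects or
  multivariate models, no power analysis.
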