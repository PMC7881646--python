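"""The permutation estimate of the metabolome-wide significance level (MWSL).

The procedure:

1. shuffle the outcome Y jointly with the covariates Z (one shared
   permutation of sample indices), leaving the features in place — this
   re-samples the subjects under the global null of no association;
2. fit the M univariate models and store the M p-values;
3. keep the minimum of the M p-values;
4. repeat K times (K at least n/2); the K minima form the null vector q;
5. the ascending (alpha*K)-th order statistic of q is the MWSL; treating
   the true position as Binomial(K, alpha) and using the Normal
   approximation gives confidence limits at positions
   (alpha*K) -/+ (1-alpha)*sqrt(alpha*K*(1-alpha));
6. ENT = alpha / MWSL is the effective number of tests and
   R = 100 * ENT / M the redundancy ratio.

Positions are real-valued; they are rounded to the nearest integer and
clamped to [1, K].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np

from . import _batched, rng
from .association import all_pvalues
from .config import RunConfig
from .datatypes import CovariateMatrix, FeatureMatrix, MinPNull, Outcome, ThresholdEstimate

logger = logging.getLogger("mwsl")


def permute_null(
    outcome: Outcome,
    X: FeatureMatrix | np.ndarray,
    covariates: CovariateMatrix | None = None,
    K: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    engine: str = "batched",
) -> MinPNull:
    """Build the minimum-p permutation null vector q of length K.

    Each replicate draws its shuffle from an independent substream of the
    root seed, so the result does not depend on evaluation order. The
    outcome (and covariates, jointly) are shuffled; features stay in place.
    """
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, M = vals.shape
    floor = ceil(n / 2)
    if K < floor:
        raise ValueError(
            f"K={K} is below the floor ceil(n/2)={floor}: the permutation count "
            "must be at least half the sample size"
        )
    if len(outcome) != n:
        raise ValueError("outcome length does not match feature rows")
    perms = rng.permutation_block(seed, K, n)

    no_cov = covariates is None or covariates.P == 0
    if engine == "batched":
        if outcome.family == "continuous" and no_cov:
            return _continuous_fast_null(outcome.values, vals, perms, M)
        return _stacked_null(outcome, vals, covariates, perms)

    q = np.empty(K)
    n_failed_total = 0
    for k in range(K):
        idx = perms[k]
        pv = all_pvalues(
            outcome.take(idx),
            vals,
            covariates.take(idx) if not no_cov else None,
            engine=engine,
        )
        q[k] = pv.min_p()
        n_failed_total += pv.n_failed
    q = np.maximum(q, np.finfo(float).tiny)
    return MinPNull(q, n_failed_total=n_failed_total, M=M)


def _stacked_null(
    outcome: Outcome,
    vals: np.ndarray,
    covariates: CovariateMatrix | None,
    perms: np.ndarray,
) -> MinPNull:
    """Batch whole replicates through the vectorised engines.

    Shuffling (Y, Z) by a permutation pi and refitting equals keeping
    (Y, Z) fixed and reordering the feature rows by pi^{-1}; each replicate
    therefore contributes M extra columns to one big stacked design, and a
    single batched call evaluates many replicates at once.
    """
    K, n = perms.shape
    M = vals.shape[1]
    Z = covariates.values if covariates is not None and covariates.P else None
    inv = np.argsort(perms, axis=1, kind="stable")
    R = max(1, int(4_000_000 // max(n * M, 1)))
    q = np.empty(K)
    n_failed_total = 0
    for lo in range(0, K, R):
        chunk = inv[lo : lo + R]
        Xbig = np.transpose(vals[chunk], (1, 0, 2)).reshape(n, -1)
        if outcome.family == "continuous":
            p = _batched.ols_pvalues(outcome.values, Xbig, Z)
        elif outcome.family in {"binary", "count"}:
            p = _batched.glm_pvalues(outcome.values, Xbig, Z, outcome.family)
        else:
            p = _batched.cox_pvalues(outcome.time, outcome.event, Xbig, Z)
        P = p.reshape(chunk.shape[0], M)
        ok = np.isfinite(P)
        if not ok.any(axis=1).all():
            raise ValueError("all model fits failed; no minimum p-value exists")
        n_failed_total += int(np.sum(~ok))
        q[lo : lo + chunk.shape[0]] = np.where(ok, P, np.inf).min(axis=1)
    q = np.maximum(q, np.finfo(float).tiny)
    return MinPNull(q, n_failed_total=n_failed_total, M=M)


def _continuous_fast_null(
    y: np.ndarray, vals: np.ndarray, perms: np.ndarray, M: int, block: int = 512
) -> MinPNull:
    """Vectorised continuous/no-covariate path: all replicates via one matmul each."""
    K = perms.shape[0]
    q = np.empty(K)
    n_failed_total = 0
    for lo in range(0, K, block):
        P = _batched.ols_pvalue_block(y[perms[lo : lo + block]], vals)
        ok = np.isfinite(P)
        if not ok.all():
            n_failed = int(np.sum(~ok))
            if not ok.any(axis=1).all():
                raise ValueError("all model fits failed; no minimum p-value exists")
            n_failed_total += n_failed
            P = np.where(ok, P, np.inf)
        q[lo : lo + block] = P.min(axis=1)
    q = np.maximum(q, np.finfo(float).tiny)
    return MinPNull(q, n_failed_total=n_failed_total, M=M)


def mwsl_from_null(q: MinPNull | np.ndarray, alpha: float = 0.05, M: int | None = None) -> ThresholdEstimate:
    """Extract the MWSL and its confidence limits from the min-p null.

    The point estimate is the ascending order statistic of q at the
    (rounded) position alpha*K; the confidence limits come from the order
    statistics at positions alpha*K -/+ (1-alpha)*sqrt(alpha*K*(1-alpha)),
    clamped to [1, K].
    """
    if isinstance(q, MinPNull):
        if M is None:
            M = q.M
        null = q
        qv = q.q
    else:
        qv = np.asarray(q, dtype=float)
        null = MinPNull(qv, M=M)
    K = null.K
    centre = alpha * K
    if round(centre) < 1:
        raise ValueError(f"K={K} too small to resolve the alpha={alpha} quantile")
    qs = np.sort(qv, kind="stable")
    offset = (1.0 - alpha) * sqrt(centre * (1.0 - alpha))
    i_mid = int(np.clip(round(centre), 1, K))
    i_lo = int(np.clip(round(centre - offset), 1, K))
    i_up = int(np.clip(round(centre + offset), 1, K))
    return ThresholdEstimate(
        mwsl=float(qs[i_mid - 1]),
        mwsl_ci_low=float(qs[i_lo - 1]),
        mwsl_ci_up=float(qs[i_up - 1]),
        alpha=alpha,
        K=K,
        M=M,
    )


@dataclass
class PermutationResult:
    """ThresholdEstimate together with the null it was extracted from."""

    threshold: ThresholdEstimate
    null: MinPNull


def run_mwsl(
    outcome: Outcome,
    X: FeatureMatrix,
    covariates: CovariateMatrix | None = None,
    config: RunConfig | None = None,
) -> PermutationResult:
    """Full MWSL estimation: optional parametric surrogate, permutation, quantile.

    With ``config.approximation`` set to ``mvnormal`` or ``mvlognormal`` the
    permutation null is built on a parametric surrogate of the features
    (drawn from the shrinkage-covariance multivariate (log-)Normal), which
    stabilises the threshold when features are skewed or heavy-tailed.
    """
    config = config or RunConfig()
    n = X.n
    K = config.resolve_K(n)
    ss = rng.root_sequence(config.seed)
    ss_feat, ss_perm = ss.spawn(2)
    if config.approximation != "identity":
        from .parametric import approximate_features

        X = approximate_features(X, method=config.approximation, n_out=n, seed=ss_feat)
        logger.info("run_mwsl: features approximated via %s", config.approximation)
    logger.info(
        "run_mwsl: alpha=%g K=%d n=%d M=%d approximation=%s seed=%s",
        config.alpha, K, n, X.M, config.approximation, config.seed,
    )
    null = permute_null(outcome, X, covariates, K=K, seed=ss_perm)
    est = mwsl_from_null(null, alpha=config.alpha, M=X.M)
    return PermutationResult(threshold=est, null=null)
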