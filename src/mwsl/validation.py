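"""Type-I-error (FWER) validation of an estimated significance threshold.

A threshold controls the family-wise error rate at level alpha if, under
the global null, the probability that *any* of the M feature tests falls at
or below the threshold is close to alpha. The harness draws fresh null
outcomes — independent of whatever produced the threshold — fits the M
univariate models per replicate, and reports the fraction of replicates
whose minimum p-value does not exceed the threshold, with a binomial
confidence interval. Per-feature rejection rates are kept as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import _batched, rng as _rng
from .association import all_pvalues
from .config import RunConfig
from .datatypes import CovariateMatrix, FeatureMatrix
from .synthetic import OutcomeSpec, gen_outcome


@dataclass
class FwerReport:
    """Estimated family-wise error rate at a fixed threshold."""

    threshold: float
    alpha: float
    K_eval: int
    fwer_hat: float
    ci_low: float
    ci_up: float
    per_feature_rates: np.ndarray
    mean_feature_rate: float  # per-test rejection rate averaged over features
    n_failed_total: int = 0


def estimate_fwer(
    X: FeatureMatrix | np.ndarray,
    outcome_spec: OutcomeSpec,
    threshold: float,
    K_eval: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    covariates: CovariateMatrix | None = None,
    alpha: float = 0.05,
) -> FwerReport:
    """Monte-Carlo FWER of ``threshold`` under fresh null outcomes.

    ``outcome_spec`` must describe a null outcome (``linkage='none'``) so
    every rejection is a false positive by construction.
    """
    if K_eval < 100:
        raise ValueError("K_eval must be at least 100 for a meaningful interval")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if outcome_spec.linkage != "none":
        raise ValueError("FWER estimation requires a null outcome (linkage='none')")
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, M = vals.shape
    ss = seed if isinstance(seed, np.random.SeedSequence) else _rng.root_sequence(seed)

    no_cov = covariates is None or covariates.P == 0
    if outcome_spec.family == "continuous" and outcome_spec.shape == "normal" and no_cov:
        hits, rates, n_failed = _fast_normal_fwer(vals, threshold, K_eval, ss)
    elif outcome_spec.family in {"binary", "count"} and no_cov:
        hits, rates, n_failed = _stacked_glm_fwer(vals, outcome_spec, threshold, K_eval, ss)
    else:
        hits = np.zeros(K_eval, dtype=bool)
        rates = np.zeros(M)
        n_failed = 0
        for k, child in enumerate(ss.spawn(K_eval)):
            y = gen_outcome(outcome_spec, n=n, seed=child)
            pv = all_pvalues(y, vals, covariates)
            n_failed += pv.n_failed
            hits[k] = pv.min_p() <= threshold
            rates += np.where(np.isfinite(pv.values), pv.values <= threshold, 0.0)
        rates /= K_eval
    fwer_hat = float(np.mean(hits))
    lo, up = proportion_confint(int(hits.sum()), K_eval, alpha=0.05, method="wilson")
    return FwerReport(
        threshold=float(threshold),
        alpha=alpha,
        K_eval=K_eval,
        fwer_hat=fwer_hat,
        ci_low=float(lo),
        ci_up=float(up),
        per_feature_rates=rates,
        mean_feature_rate=float(np.mean(rates)),
        n_failed_total=n_failed,
    )


def _fast_normal_fwer(
    vals: np.ndarray, threshold: float, K_eval: int, ss: np.random.SeedSequence, block: int = 512
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised path: Gaussian null outcomes in blocks, one matmul per block."""
    n, M = vals.shape
    children = ss.spawn(K_eval)
    hits = np.zeros(K_eval, dtype=bool)
    rates = np.zeros(M)
    n_failed = 0
    for lo_i in range(0, K_eval, block):
        chunk = children[lo_i : lo_i + block]
        Y = np.stack([np.random.Generator(np.random.PCG64(c)).standard_normal(n) for c in chunk])
        P = _batched.ols_pvalue_block(Y, vals)
        ok = np.isfinite(P)
        n_failed += int(np.sum(~ok))
        Pw = np.where(ok, P, np.inf)
        hits[lo_i : lo_i + block] = Pw.min(axis=1) <= threshold
        rates += (Pw <= threshold).sum(axis=0)
    return hits, rates / K_eval, n_failed


def permutation_fwer(
    X: FeatureMatrix | np.ndarray,
    outcome,
    threshold: float,
    K_eval: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    covariates: CovariateMatrix | None = None,
    alpha: float = 0.05,
) -> FwerReport:
    """FWER of ``threshold`` across independent permutation replicates.

    This is the evaluation matching the permutation procedure itself: the
    null replicates are fresh, independent shuffles of the *same* outcome
    realisation (never the shuffles that produced the threshold), so the
    check probes the conditional null the threshold was extracted from.
    Use :func:`estimate_fwer` to marginalise over outcome redraws instead;
    with skewed features and discrete outcomes the min-p distribution
    varies between outcome realisations, and only the conditional check
    reflects the procedure as deployed on one study.

    Per-feature rates are not collected on this path.
    """
    from .permutation import permute_null

    if K_eval < 100:
        raise ValueError("K_eval must be at least 100 for a meaningful interval")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    M = vals.shape[1]
    null = permute_null(outcome, vals, covariates, K=K_eval, seed=seed)
    hits = null.q <= threshold
    fwer_hat = float(np.mean(hits))
    lo, up = proportion_confint(int(hits.sum()), K_eval, alpha=0.05, method="wilson")
    return FwerReport(
        threshold=float(threshold),
        alpha=alpha,
        K_eval=K_eval,
        fwer_hat=fwer_hat,
        ci_low=float(lo),
        ci_up=float(up),
        per_feature_rates=np.full(M, np.nan),
        mean_feature_rate=float("nan"),
        n_failed_total=null.n_failed_total,
    )


def _stacked_glm_fwer(
    vals: np.ndarray,
    outcome_spec: OutcomeSpec,
    threshold: float,
    K_eval: int,
    ss: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Batch fresh binary/count null outcomes through one IRLS call per block.

    Each replicate contributes M stacked models sharing the replicate's
    outcome column; the per-model-outcome form of the batched GLM engine
    evaluates a whole block at once.
    """
    n, M = vals.shape
    children = ss.spawn(K_eval)
    R = max(1, int(4_000_000 // max(n * M, 1)))
    hits = np.zeros(K_eval, dtype=bool)
    rates = np.zeros(M)
    n_failed = 0
    for lo in range(0, K_eval, R):
        chunk = children[lo : lo + R]
        Y = np.stack([gen_outcome(outcome_spec, n=n, seed=c).values for c in chunk], axis=1)
        Rc = Y.shape[1]
        Xbig = np.tile(vals, (1, Rc))
        Ybig = np.repeat(Y, M, axis=1)
        p = _batched.glm_pvalues(Ybig, Xbig, None, outcome_spec.family)
        P = p.reshape(Rc, M)
        ok = np.isfinite(P)
        n_failed += int(np.sum(~ok))
        Pw = np.where(ok, P, np.inf)
        hits[lo : lo + Rc] = Pw.min(axis=1) <= threshold
        rates += (Pw <= threshold).sum(axis=0)
    return hits, rates / K_eval, n_failed


def validation_suite(
    X: FeatureMatrix,
    families: tuple[str, ...] = ("continuous", "binary", "count", "survival"),
    approximations: tuple[str, ...] = ("identity", "mvnormal", "mvlognormal"),
    alpha: float = 0.05,
    K: int = 2000,
    K_eval: int = 2000,
    seed: int = 0,
    outcome_specs: dict[str, OutcomeSpec] | None = None,
) -> pd.DataFrame:
    """FWER / ENT grid over outcome families x feature approximations.

    For each cell the feature approximation is drawn once, the threshold is
    estimated by the permutation procedure on those features, and the
    type-I error is then measured across fresh, independent permutation
    replicates on the same features and outcome — never the replicates
    that produced the threshold. This probes the conditional null the
    procedure actually thresholds; see :func:`permutation_fwer`.
    """
    specs = outcome_specs or {f: OutcomeSpec(family=f) for f in families}
    rows = []
    ss = _rng.root_sequence(seed)
    for a_i, approx in enumerate(approximations):
        for f_i, fam in enumerate(families):
            spec = specs[fam]
            cell = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(a_i, f_i)
            )
            ss_out, ss_perm, ss_eval = cell.spawn(3)
            y = gen_outcome(spec, n=X.n, seed=ss_out)
            cfg = RunConfig(alpha=alpha, K=K, seed=0, approximation=approx)
            # reuse the cell's substream for the permutation stage
            res, feats = _run_with_streams(y, X, cfg, ss_perm)
            rep = permutation_fwer(feats, y, res.threshold.mwsl, K_eval=K_eval, seed=ss_eval, alpha=alpha)
            rows.append(
                {
                    "approximation": approx,
                    "family": fam,
                    "ent": res.threshold.ent,
                    "ent_ci_low": res.threshold.ent_ci_low,
                    "ent_ci_up": res.threshold.ent_ci_up,
                    "r_ratio": res.threshold.r_ratio,
                    "mwsl": res.threshold.mwsl,
                    "fwer_pct": 100.0 * rep.fwer_hat,
                    "fwer_ci_low_pct": 100.0 * rep.ci_low,
                    "fwer_ci_up_pct": 100.0 * rep.ci_up,
                    "mean_feature_rate_pct": 100.0 * rep.mean_feature_rate,
                }
            )
    return pd.DataFrame(rows)


def _run_with_streams(y, X: FeatureMatrix, cfg: RunConfig, ss: np.random.SeedSequence):
    """run_mwsl with an explicit SeedSequence; returns the features used."""
    from .parametric import approximate_features
    from .permutation import PermutationResult, mwsl_from_null, permute_null

    ss_feat, ss_perm = ss.spawn(2)
    feats = X
    if cfg.approximation != "identity":
        feats = approximate_features(X, method=cfg.approximation, n_out=X.n, seed=ss_feat)
    K = cfg.resolve_K(X.n)
    null = permute_null(y, feats, None, K=K, seed=ss_perm)
    est = mwsl_from_null(null, alpha=cfg.alpha, M=feats.M)
    return PermutationResult(threshold=est, null=null), feats
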