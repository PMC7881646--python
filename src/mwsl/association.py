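"""Univariate association testing: one feature at a time against the outcome.

This is the engine the permutation procedure calls M times per shuffle
replicate. The model family follows the outcome family:

==========  =====================================  ==================
family      model                                  feature test
==========  =====================================  ==================
continuous  linear model (OLS)                     Wald t
binary      logistic regression                    Wald z
count       log-linear Poisson regression          Wald z
survival    Cox proportional hazards (Efron ties)  Wald z
==========  =====================================  ==================

Covariates are always included as fixed effects. ``feature_pvalue`` fits a
single model through statsmodels / lifelines and additionally offers a
likelihood-ratio test and, for continuous outcomes, a plain correlation
test. ``all_pvalues`` dispatches to the batched engines in
:mod:`mwsl._batched`, which replicate the single-model Wald fits at a small
fraction of the cost; degenerate fits come back as NaN and are excluded from
the minimum rather than polluting it with a spurious zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import _batched
from .datatypes import CovariateMatrix, FeatureMatrix, Outcome, PValueVector


def _cov_values(covariates: CovariateMatrix | None) -> np.ndarray | None:
    if covariates is None or covariates.P == 0:
        return None
    return covariates.values


def feature_pvalue(
    outcome: Outcome,
    feature: np.ndarray,
    covariates: CovariateMatrix | None = None,
    stat: str = "wald",
) -> float:
    """Two-sided p-value of the feature coefficient in a single univariate model.

    ``stat`` selects the test: ``wald`` (default), ``lrt`` (likelihood
    ratio), or — continuous outcomes only — ``correlation`` (Pearson test,
    identical to the OLS Wald t without covariates).

    Returns NaN when the fit fails (zero-variance feature, separation,
    non-convergence); a failed fit is never reported as p=0.
    """
    import statsmodels.api as sm

    feature = np.asarray(feature, dtype=float)
    Z = _cov_values(covariates)
    if stat == "correlation":
        if outcome.family != "continuous":
            raise ValueError("correlation test applies to continuous outcomes only")
        if covariates is not None and covariates.P > 0:
            raise ValueError("correlation test does not support covariates")
        if np.std(feature) == 0 or np.std(outcome.values) == 0:
            return float("nan")
        return float(stats.pearsonr(outcome.values, feature).pvalue)
    if stat not in {"wald", "lrt"}:
        raise ValueError(f"unknown test statistic {stat!r}")

    n = len(outcome)
    design = np.column_stack([np.ones(n), feature] if Z is None else [np.ones(n), Z, feature])
    j = design.shape[1] - 1  # feature coefficient index

    try:
        if outcome.family == "survival":
            return _cox_single(outcome, feature, Z, stat)
        if outcome.family == "continuous":
            model = sm.OLS(outcome.values, design)
        elif outcome.family == "binary":
            model = sm.GLM(outcome.values, design, family=sm.families.Binomial())
        else:
            model = sm.GLM(outcome.values, design, family=sm.families.Poisson())
        res = model.fit()
        if stat == "lrt":
            null_res = type(model)(
                outcome.values, design[:, :j], **({} if outcome.family == "continuous" else {"family": model.family})
            ).fit()
            llr = 2.0 * (res.llf - null_res.llf)
            return float(stats.chi2.sf(max(llr, 0.0), df=1))
        p = float(res.pvalues[j])
        if not np.isfinite(p) or float(res.bse[j]) > _batched._SE_FAIL:
            return float("nan")
        return p
    except (np.linalg.LinAlgError, ValueError):
        return float("nan")


def _cox_single(outcome: Outcome, feature: np.ndarray, Z: np.ndarray | None, stat: str) -> float:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = {"time": outcome.time, "event": outcome.event, "x": feature}
    covs = []
    if Z is not None:
        for k in range(Z.shape[1]):
            cols[f"z{k}"] = Z[:, k]
            covs.append(f"z{k}")
    df = pd.DataFrame(cols)
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        if stat == "lrt":
            ll_full = cph.log_likelihood_
            if covs:
                null = CoxPHFitter()
                null.fit(df[["time", "event"] + covs], duration_col="time", event_col="event")
                ll_null = null.log_likelihood_
            else:
                null = CoxPHFitter()
                null.fit(df[["time", "event"]], duration_col="time", event_col="event")
                ll_null = null.log_likelihood_
            return float(stats.chi2.sf(max(2.0 * (ll_full - ll_null), 0.0), df=1))
        p = float(cph.summary.loc["x", "p"])
        if not np.isfinite(p) or float(cph.summary.loc["x", "se(coef)"]) > _batched._SE_FAIL:
            return float("nan")
        return p
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return float("nan")


def all_pvalues(
    outcome: Outcome,
    X: FeatureMatrix | np.ndarray,
    covariates: CovariateMatrix | None = None,
    engine: str = "batched",
) -> PValueVector:
    """P-values of all M feature coefficients for one outcome realisation.

    ``engine='batched'`` (default) uses the vectorised fits;
    ``engine='reference'`` loops :func:`feature_pvalue` — slow, used for
    cross-validation of the batched code paths.
    """
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[0] != len(outcome):
        raise ValueError("feature rows do not match outcome length")
    Z = _cov_values(covariates)
    if engine == "reference":
        p = np.array([feature_pvalue(outcome, vals[:, m], covariates) for m in range(vals.shape[1])])
    elif engine == "batched":
        if outcome.family == "continuous":
            p = _batched.ols_pvalues(outcome.values, vals, Z)
        elif outcome.family in {"binary", "count"}:
            p = _batched.glm_pvalues(outcome.values, vals, Z, outcome.family)
        else:
            p = _batched.cox_pvalues(outcome.time, outcome.event, vals, Z)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return PValueVector(p)


def min_pvalue(
    outcome: Outcome,
    X: FeatureMatrix | np.ndarray,
    covariates: CovariateMatrix | None = None,
    engine: str = "batched",
) -> tuple[float, int]:
    """Minimum p-value over non-failed fits plus the failed-fit count."""
    pv = all_pvalues(outcome, X, covariates, engine=engine)
    return pv.min_p(), pv.n_failed
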