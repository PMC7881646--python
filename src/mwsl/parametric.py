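"""Parametric approximation of the feature matrix.

Metabolic profiles are rarely Normal, and a single badly calibrated test is
enough to bias the minimum-p null. The cure used here is to replace the raw
features with surrogates drawn from a multivariate Normal (or, for
right-skewed profiles, a shifted multivariate log-Normal) whose covariance
is the shrinkage estimator Sigma* — always positive definite and
well-conditioned even when features outnumber samples — so the surrogate
preserves the correlation structure up to second-order moments while having
well-behaved margins.

The shrinkage estimator follows the analytic linear-shrinkage recipe of
Schafer & Strimmer (2005) with a diagonal, unequal-variance target: the
off-diagonal correlations are shrunk toward zero with the data-driven
intensity

    lambda* = sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2,   clipped to [0, 1],

and the sample variances are kept on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rng as _rng
from .datatypes import FeatureMatrix


@dataclass
class ShrunkCovariance:
    """Positive-definite shrinkage covariance Sigma* and its intensity."""

    sigma_star: np.ndarray
    shrinkage_intensity: float
    variances: np.ndarray  # diagonal of Sigma* (sample variances)
    correlation: np.ndarray  # shrunk correlation matrix R*


@dataclass
class ShiftRecord:
    """Per-feature additive shifts applied before the log transform."""

    shifts: np.ndarray


def shrink_covariance(X: FeatureMatrix | np.ndarray) -> ShrunkCovariance:
    """Analytic linear-shrinkage covariance estimate (diagonal target).

    Raises on constant features: a zero variance has no correlation scale
    to shrink toward.
    """
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, M = vals.shape
    if n < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    var = vals.var(axis=0, ddof=1)
    if np.any(var <= 0):
        bad = int(np.argmax(var <= 0))
        raise ValueError(f"constant feature at column {bad}: zero variance breaks shrinkage")
    Xc = vals - vals.mean(axis=0, keepdims=True)
    Xs = Xc / np.sqrt(var)
    r = (Xs.T @ Xs) / (n - 1)  # sample correlation, unit diagonal
    # Var-hat(r_ij) via sums of squared cross products: w_kij = xs_ki * xs_kj
    W2 = (Xs * Xs).T @ (Xs * Xs)  # sum_k w_kij^2
    wbar = (n - 1) / n * r
    var_r = n / (n - 1) ** 3 * (W2 - n * wbar**2)
    off = ~np.eye(M, dtype=bool)
    denom = float(np.sum(r[off] ** 2))
    lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    R = (1.0 - lam) * r
    np.fill_diagonal(R, 1.0)
    sd = np.sqrt(var)
    sigma = R * np.outer(sd, sd)
    sigma = 0.5 * (sigma + sigma.T)
    return ShrunkCovariance(sigma_star=sigma, shrinkage_intensity=lam, variances=var, correlation=R)


def shift_for_log(X: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, ShiftRecord]:
    """Shift every feature by |min| + 1 so logs are defined and >= 0.

    The rule is applied literally to each column regardless of sign: a
    feature with minimum -3 is shifted by 4 (new minimum 1), one with
    minimum 2 is shifted by 3 (new minimum 5).
    """
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    shifts = np.abs(vals.min(axis=0)) + 1.0
    return vals + shifts[None, :], ShiftRecord(shifts=shifts)


def approximate_features(
    X: FeatureMatrix,
    method: str,
    n_out: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    skew_trigger: float | None = None,
) -> FeatureMatrix:
    """Draw a surrogate feature matrix from the fitted parametric model.

    ``mvnormal``: centre the features, estimate Sigma*, and draw n_out rows
    from N(0, Sigma*). ``mvlognormal``: shift each feature by |min|+1, take
    natural logs, estimate Sigma* on the log scale, draw from the
    multivariate Normal with the log-scale means, and exponentiate —
    surrogates are strictly positive and right-skewed like the source.

    ``skew_trigger``: if set (e.g. 1.0), the log transform is applied only
    to features whose sample skewness exceeds the trigger; by default all
    features are transformed when ``mvlognormal`` is selected.
    """
    if method not in {"mvnormal", "mvlognormal"}:
        raise ValueError(f"unknown approximation method {method!r}")
    n_out = X.n if n_out is None else int(n_out)
    gen = _rng.generator(seed)
    vals = X.values
    if method == "mvnormal":
        sc = shrink_covariance(vals - vals.mean(axis=0, keepdims=True))
        draw = _draw_mvn(np.zeros(X.M), sc, n_out, gen)
    else:
        if skew_trigger is not None:
            from scipy.stats import skew

            do_log = skew(vals, axis=0, bias=False) > skew_trigger
        else:
            do_log = np.ones(X.M, dtype=bool)
        shifted, _ = shift_for_log(vals)
        work = vals.copy()
        work[:, do_log] = np.log(shifted[:, do_log])
        mu = work.mean(axis=0)
        sc = shrink_covariance(work - mu[None, :])
        draw = _draw_mvn(mu, sc, n_out, gen)
        draw[:, do_log] = np.exp(draw[:, do_log])
    sample_ids = [f"s{i}" for i in range(n_out)]
    return FeatureMatrix(draw, list(X.feature_ids), sample_ids)


def _draw_mvn(mu: np.ndarray, sc: ShrunkCovariance, n_out: int, gen: np.random.Generator) -> np.ndarray:
    try:
        L = np.linalg.cholesky(sc.sigma_star)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - Sigma* is PD by construction
        raise RuntimeError("Cholesky failed on the shrinkage covariance") from exc
    E = gen.standard_normal((n_out, mu.size))
    return mu[None, :] + E @ L.T
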