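"""Closed-form effective-number-of-tests (Meff) estimators.

The collective correlation of M variates is summarised by the eigenvalues
lambda_1 >= ... >= lambda_M of their correlation matrix: under independence
all eigenvalues equal 1; under complete correlation lambda_1 = M and the
rest vanish. Each estimator maps this spectrum to a permutation-free
estimate of the effective number of tests:

* ``mwsl``   — the spectral-balance formula
  Meff = ((sum_m sqrt(lambda_m)) / ln(lambda_1))^2
         / ((sum_m lambda_m)/lambda_1 + sqrt(lambda_1)),
  defined for lambda_1 > 1 (i.e. at least two correlated variates);
* ``nyholt`` — 1 + (M-1) * (1 - Var(lambda)/M), sample variance;
* ``liji``   — sum_m min(lambda_m, 1) (substitute 1 for eigenvalues above 1,
  then sum); the canonical Li-Ji floor/fraction form is available as
  ``liji_canonical``;
* ``gao``    — smallest k whose leading eigenvalues explain a fraction
  (default 0.995) of the total variance;
* ``galwey`` — (sum_m sqrt(lambda_m))^2 / sum_m lambda_m.

From a Meff value the study-wide threshold follows either by Bonferroni
(MWSL = alpha/Meff) or by modelling the minimum of Meff independent uniform
p-values as Beta(1, Meff) and taking its alpha-quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np

from . import rng as _rng
from .datatypes import FeatureMatrix, ThresholdEstimate
from .permutation import mwsl_from_null

_EIG_NEG_TOL = 1e-8

ALTERNATIVE_METHODS = ("nyholt", "liji", "liji_canonical", "gao", "galwey")


@dataclass
class EigenSpectrum:
    """Descending eigenvalues of a correlation matrix."""

    lambdas: np.ndarray
    M: int
    rank: int

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.M = int(self.M)
        total = float(np.sum(self.lambdas))
        if abs(total - self.M) > 1e-6 * self.M:
            raise ValueError(
                f"eigenvalue sum {total:g} violates the trace rule (expected M={self.M})"
            )


@dataclass
class MeffEstimate:
    method: str
    value: float
    r_ratio: float

    @property
    def rounded(self) -> int:
        return int(round(self.value))


def eigen_spectrum(source, is_correlation: bool | None = None) -> EigenSpectrum:
    """Eigen-decompose the (Pearson) correlation matrix of the features.

    ``source`` may be a FeatureMatrix, a raw n x M data array, or a
    precomputed correlation matrix; a square symmetric unit-diagonal array
    is auto-detected as a correlation matrix unless ``is_correlation``
    says otherwise.
    """
    if isinstance(source, FeatureMatrix):
        a = source.values
        is_correlation = False
    else:
        a = np.asarray(source, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-d array")
    if is_correlation is None:
        is_correlation = (
            a.shape[0] == a.shape[1]
            and np.allclose(np.diag(a), 1.0, atol=1e-8)
            and np.allclose(a, a.T, atol=1e-8)
        )
    if is_correlation:
        if a.shape[0] != a.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric within tolerance")
        corr = 0.5 * (a + a.T)
    else:
        sd = a.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("constant feature: correlation undefined")
        corr = np.corrcoef(a, rowvar=False)
    M = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)[::-1].copy()
    if lam[-1] < -_EIG_NEG_TOL * max(1.0, lam[0]):
        raise ValueError(f"eigenvalue {lam[-1]:g} is negative beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    rank = int(np.sum(lam > _EIG_NEG_TOL * max(1.0, lam[0])))
    return EigenSpectrum(lambdas=lam, M=M, rank=rank)


def meff_mwsl(spec: EigenSpectrum, log_base: float | None = None) -> MeffEstimate:
    """Spectral-balance Meff; requires lambda_1 > 1 (correlated variates).

    ``log_base`` selects the base of log(lambda_1); the default is the
    natural logarithm.
    """
    lam = spec.lambdas
    lam1 = float(lam[0])
    if lam1 <= 1.0 + 1e-12:
        raise ValueError(
            "meff_mwsl requires lambda_1 > 1: the formula is defined only for "
            "correlated variates (log(lambda_1) must be positive)"
        )
    log_lam1 = log(lam1) if log_base is None else log(lam1) / log(log_base)
    num = (np.sum(np.sqrt(lam)) / log_lam1) ** 2
    den = np.sum(lam) / lam1 + sqrt(lam1)
    value = float(num / den)
    return MeffEstimate("mwsl", value, 100.0 * value / spec.M)


def meff_alternatives(
    spec: EigenSpectrum,
    method: str,
    gao_fraction: float = 0.995,
    nyholt_variance: str = "sample",
) -> MeffEstimate:
    """Comparator Meff estimators from the same eigen-spectrum."""
    lam = spec.lambdas
    M = spec.M
    if method == "nyholt":
        ddof = 1 if nyholt_variance == "sample" else 0
        value = 1.0 + (M - 1) * (1.0 - float(np.var(lam, ddof=ddof)) / M)
    elif method == "liji":
        value = float(np.sum(np.minimum(lam, 1.0)))
    elif method == "liji_canonical":
        # floor/fraction form: sum_m [1(lam_m >= 1) + (lam_m - floor(lam_m))]
        value = float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    elif method == "gao":
        if not (0 < gao_fraction < 1):
            raise ValueError("gao_fraction must lie in (0, 1)")
        frac = np.cumsum(lam) / np.sum(lam)
        value = float(np.searchsorted(frac, gao_fraction - 1e-12) + 1)
    elif method == "galwey":
        value = float(np.sum(np.sqrt(lam)) ** 2 / np.sum(lam))
    else:
        raise ValueError(f"unknown method {method!r}; choose from {ALTERNATIVE_METHODS}")
    return MeffEstimate(method, value, 100.0 * value / M)


def all_meff(
    spec: EigenSpectrum, gao_fraction: float = 0.995, include_mwsl: bool = True
) -> dict[str, MeffEstimate]:
    """All estimators on one spectrum (mwsl omitted when lambda_1 <= 1)."""
    out: dict[str, MeffEstimate] = {}
    if include_mwsl and spec.lambdas[0] > 1.0 + 1e-12:
        out["mwsl"] = meff_mwsl(spec)
    for m in ("nyholt", "liji", "gao", "galwey"):
        out[m] = meff_alternatives(spec, m, gao_fraction=gao_fraction)
    return out


def bonferroni_mwsl(meff: float, alpha: float = 0.05) -> float:
    """Bonferroni shortcut: the threshold alpha / Meff."""
    if meff < 1:
        raise ValueError("meff must be at least 1")
    return alpha / meff


def beta_approx_mwsl(
    meff: float,
    alpha: float = 0.05,
    K: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    mode: str = "sample",
    M: int | None = None,
) -> ThresholdEstimate:
    """Permutation-free MWSL via the Beta(1, Meff) minimum-p model.

    Under the null each of Meff effectively independent p-values is
    U(0,1), so their minimum is Beta(1, Meff); with Meff = 1 this is
    U(0,1) itself. ``sample`` mode draws K values and reuses the
    order-statistic machinery of the permutation procedure; ``analytic``
    evaluates the Beta quantile 1 - (1-alpha)^(1/Meff) directly, with
    confidence limits taken at the same order-statistic positions.
    """
    if meff < 1:
        raise ValueError("meff must be at least 1")
    if mode == "sample":
        gen = _rng.generator(seed)
        q = gen.beta(1.0, meff, size=K)
        q = np.maximum(q, np.finfo(float).tiny)
        return mwsl_from_null(q, alpha=alpha, M=M)
    if mode == "analytic":
        K = int(K)
        centre = alpha * K
        if round(centre) < 1:
            raise ValueError(f"K={K} too small to resolve the alpha={alpha} quantile")
        offset = (1.0 - alpha) * sqrt(centre * (1.0 - alpha))
        def beta_q(pos: float) -> float:
            level = np.clip(round(pos), 1, K) / K
            return float(1.0 - (1.0 - level) ** (1.0 / meff))
        return ThresholdEstimate(
            mwsl=beta_q(centre),
            mwsl_ci_low=beta_q(centre - offset),
            mwsl_ci_up=beta_q(centre + offset),
            alpha=alpha,
            K=K,
            M=M,
        )
    raise ValueError(f"unknown mode {mode!r}")
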