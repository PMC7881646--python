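"""Synthetic inputs: correlated feature sets, outcomes of four families,
and PCA-based nonparametric surrogate features.

The feature generator produces Gaussian variates whose pairwise correlations
sit inside a prescribed band; nine presets cover the positive correlation
range from near-independence (0, 0.25) up to near-collinearity [0.95, 1).
Outcomes are either independent of the features (the null used throughout
type-I-error work) or coupled to them through a linear combination or a
latent-factor (Cholesky-style) construction.

Defaults mirror a serum NMR profiling setting: M = 650 variates and
n = 3500 samples, with K = 5000 permutations at simulation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import rng as _rng
from .datatypes import FeatureMatrix, Outcome


@dataclass(frozen=True)
class CorrelationBand:
    """Half-open band [low, high) of pairwise correlation levels."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError(f"invalid correlation band [{self.low}, {self.high})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def name(self) -> str:
        return f"[{self.low:g},{self.high:g})"


#: The nine presets spanning the positive correlation range, strongest first.
BAND_PRESETS: tuple[CorrelationBand, ...] = (
    CorrelationBand(0.95, 1.0),
    CorrelationBand(0.85, 0.95),
    CorrelationBand(0.75, 0.85),
    CorrelationBand(0.65, 0.75),
    CorrelationBand(0.55, 0.65),
    CorrelationBand(0.45, 0.55),
    CorrelationBand(0.35, 0.45),
    CorrelationBand(0.25, 0.35),
    CorrelationBand(0.0, 0.25),
)

#: The nine-band simulation scenario: M=650 variates per band at study scale.
NINE_BAND_SCENARIO = {"M": 650, "n": 3500, "K": 5000, "bands": BAND_PRESETS}


def _nearest_pd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    lam, V = np.linalg.eigh(0.5 * (R + R.T))
    lam = np.clip(lam, eps, None)
    A = (V * lam) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return 0.5 * (A + A.T)


def _mean_offdiag_corr(X: np.ndarray) -> float:
    R = np.corrcoef(X, rowvar=False)
    M = R.shape[0]
    return float((R.sum() - M) / (M * (M - 1)))


def gen_correlated_features(
    M: int,
    n: int,
    band: CorrelationBand,
    structure: str = "equicorrelated",
    seed: int | np.random.SeedSequence = 0,
    max_retries: int = 5,
) -> FeatureMatrix:
    """Gaussian features whose mean pairwise correlation lands inside the band.

    ``equicorrelated``: constant pairwise correlation at the band midpoint,
    generated as sqrt(rho) * shared factor + sqrt(1-rho) * noise (the
    Cholesky factor of compound symmetry in closed form).
    ``random-within-band``: target off-diagonals drawn uniformly inside the
    band, projected to the nearest positive-definite correlation matrix,
    then sampled through its Cholesky factor.

    The draw is rejected and retried (fresh substream, up to
    ``max_retries``) if the empirical mean off-diagonal correlation falls
    outside the band.
    """
    if M < 2 or n < 3:
        raise ValueError("need M >= 2 features and n >= 3 samples")
    if structure not in {"equicorrelated", "random-within-band"}:
        raise ValueError(f"unknown structure {structure!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else _rng.root_sequence(seed)
    last_mean = None
    for child in ss.spawn(max_retries):
        gen = np.random.Generator(np.random.PCG64(child))
        if structure == "equicorrelated":
            rho = band.midpoint
            g = gen.standard_normal((n, 1))
            E = gen.standard_normal((n, M))
            X = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * E
        else:
            R = np.ones((M, M))
            iu = np.triu_indices(M, k=1)
            vals = gen.uniform(band.low, band.high, size=iu[0].size)
            R[iu] = vals
            R[(iu[1], iu[0])] = vals
            R = _nearest_pd_correlation(R)
            L = np.linalg.cholesky(R)
            X = gen.standard_normal((n, M)) @ L.T
        last_mean = _mean_offdiag_corr(X)
        lo = band.low if band.low > 0 else -1.0  # open lower bound at 0
        if lo <= last_mean <= band.high:
            return FeatureMatrix(
                X, [f"f{j}" for j in range(M)], [f"s{i}" for i in range(n)]
            )
    raise RuntimeError(
        f"could not land mean off-diagonal correlation in {band.name} after "
        f"{max_retries} attempts (last mean {last_mean:.4f})"
    )


@dataclass
class OutcomeSpec:
    """Recipe for a synthetic outcome.

    ``linkage='none'`` draws the outcome independently of the features (the
    null configuration); ``'linear'`` builds it from a weighted combination
    of features plus Gaussian noise; ``'cholesky'`` couples the latent
    response to the features' common factor at ``target_corr``.
    """

    family: str = "continuous"
    shape: str = "normal"  # continuous only: normal | skewnormal | weibull
    loc: float = 0.0
    scale: float = 1.0
    skew: float = 5.0  # skew-normal shape parameter
    weibull_shape: float = 0.8  # shape < 1 gives a strongly right-skewed outcome
    prob: float = 0.5  # binary success probability
    rate: float = 1.0  # count (Poisson) rate
    baseline_hazard: float = 0.1
    censoring: float = 0.3  # target censored fraction
    linkage: str = "none"
    weights: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    target_corr: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in {"continuous", "binary", "count", "survival"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.linkage not in {"none", "linear", "cholesky"}:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not (0 < self.prob < 1):
            raise ValueError("prob must lie in (0, 1)")
        if self.rate <= 0 or self.scale <= 0 or self.baseline_hazard <= 0:
            raise ValueError("rate, scale and baseline_hazard must be positive")
        if not (0 <= self.censoring < 1):
            raise ValueError("censoring fraction must lie in [0, 1)")


def gen_outcome(
    spec: OutcomeSpec,
    X: FeatureMatrix | None = None,
    n: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Outcome:
    """Draw an outcome of the requested family, optionally coupled to X.

    The returned Outcome carries an ``info`` dict with the realised
    feature-outcome correlations (linear linkage) and the realised
    censoring fraction (survival).
    """
    if spec.linkage != "none" and X is None:
        raise ValueError(f"linkage {spec.linkage!r} requires a feature matrix")
    if n is None:
        if X is None:
            raise ValueError("n is required when no feature matrix is given")
        n = X.n
    gen = _rng.generator(seed)
    info: dict = {}

    lp = np.zeros(n)
    if spec.linkage == "linear":
        if not spec.weights:
            raise ValueError("linear linkage requires feature weights")
        bad = [j for j in spec.weights if not (0 <= j < X.M)]
        if bad:
            raise ValueError(f"weights reference missing feature indices {bad}")
        for j, w in spec.weights.items():
            lp = lp + w * X.values[:, j]
    elif spec.linkage == "cholesky":
        common = X.values.mean(axis=1)
        u = (common - common.mean()) / common.std()
        rho = spec.target_corr
        lp = rho * u + np.sqrt(max(1.0 - rho * rho, 0.0)) * gen.standard_normal(n)

    if spec.family == "continuous":
        if spec.linkage == "linear":
            y = spec.loc + lp + gen.normal(0.0, spec.noise_sd, size=n)
        elif spec.linkage == "cholesky":
            y = spec.loc + spec.scale * lp
        elif spec.shape == "normal":
            y = gen.normal(spec.loc, spec.scale, size=n)
        elif spec.shape == "skewnormal":
            y = stats.skewnorm.rvs(spec.skew, loc=spec.loc, scale=spec.scale, size=n, random_state=gen)
        elif spec.shape == "weibull":
            y = spec.loc + spec.scale * gen.weibull(spec.weibull_shape, size=n)
        else:
            raise ValueError(f"unknown continuous shape {spec.shape!r}")
        out = Outcome("continuous", y)
    elif spec.family == "binary":
        p = stats.logistic.cdf(lp + stats.logistic.ppf(spec.prob)) if spec.linkage != "none" else np.full(n, spec.prob)
        out = Outcome("binary", gen.binomial(1, p).astype(float))
    elif spec.family == "count":
        mu = spec.rate * np.exp(lp) if spec.linkage != "none" else np.full(n, spec.rate)
        out = Outcome("count", gen.poisson(mu).astype(float))
    else:
        out = _gen_survival(spec, lp, n, gen, info)

    if spec.linkage == "linear":
        info["realized_corr"] = {
            j: float(np.corrcoef(out.values, X.values[:, j])[0, 1]) for j in spec.weights
        }
    out.info = info  # type: ignore[attr-defined]
    return out


def _gen_survival(
    spec: OutcomeSpec, lp: np.ndarray, n: int, gen: np.random.Generator, info: dict
) -> Outcome:
    """Exponential-baseline proportional-hazards times with uniform censoring.

    T = -log(U) / (h0 * exp(lp)) by inverse transform; the censoring upper
    bound is solved so the expected censored fraction matches the target.
    """
    u = gen.uniform(size=n)
    T = -np.log(u) / (spec.baseline_hazard * np.exp(lp))
    if spec.censoring <= 0:
        return Outcome("survival", None, time=T, event=np.ones(n))

    # sample i is censored when C_i < T_i; with C ~ U(0, c) that happens
    # with probability min(T_i/c, 1), so the expected censored fraction is
    # mean_i min(T_i/c, 1), monotone decreasing in c.
    def expected(c: float) -> float:
        return float(np.mean(np.minimum(T / c, 1.0))) - spec.censoring

    lo, hi = 1e-9, float(np.max(T)) * 10.0
    if expected(hi) > 0:  # even huge windows censor too much (should not happen)
        c_max = hi
    else:
        c_max = float(optimize.brentq(expected, lo, hi))
    C = gen.uniform(0.0, c_max, size=n)
    event = (T <= C).astype(float)
    time = np.minimum(T, C)
    time = np.maximum(time, np.finfo(float).tiny)
    info["realized_censoring"] = float(np.mean(1.0 - event))
    info["censoring_bound"] = c_max
    return Outcome("survival", None, time=time, event=event)


def pca_surrogate(
    X: FeatureMatrix,
    n_test: int,
    n_pcs: int,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[FeatureMatrix, dict]:
    """Nonparametric surrogate features via train/test PCA reconstruction.

    The samples are split into a test set (``n_test`` rows) and a non-test
    set; a PCA model fitted on the non-test rows projects the test rows
    onto its top ``n_pcs`` components and reconstructs them. The
    reconstruction inherits the real data's dominant correlation structure
    without reusing any permutation machinery.
    """
    from sklearn.decomposition import PCA

    if n_test >= X.n:
        raise ValueError("n_test must be smaller than the number of samples")
    n_nontest = X.n - n_test
    max_pcs = min(n_nontest - 1, X.M)
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds the non-test rank bound {max_pcs}")
    gen = _rng.generator(seed)
    idx = gen.permutation(X.n)
    test_idx, nontest_idx = idx[:n_test], idx[n_test:]
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pca.fit(X.values[nontest_idx])
    scores = pca.transform(X.values[test_idx])
    recon = pca.inverse_transform(scores)
    fm = FeatureMatrix(
        recon, list(X.feature_ids), [X.sample_ids[i] for i in test_idx]
    )
    info = {
        "test_idx": test_idx,
        "nontest_idx": nontest_idx,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    return fm, info
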