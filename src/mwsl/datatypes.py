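"""Core in-memory containers shared across the toolkit.

The central objects of a metabolome-wide association study (MWAS) are a
feature matrix (n samples x M metabolic variates), an outcome vector with a
declared model family, and an optional matrix of fixed-effect covariates.
The permutation machinery summarises its result as a :class:`ThresholdEstimate`
holding the metabolome-wide significance level (MWSL), its confidence limits,
and the implied effective number of tests (ENT = alpha / MWSL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OUTCOME_FAMILIES = ("continuous", "binary", "count", "survival")


@dataclass
class FeatureMatrix:
    """n x M matrix of metabolic variates with sample and feature labels."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        n, m = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {m} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature ids must be unique")
        if n < 2 or m < 2:
            raise ValueError("need at least 2 samples and 2 features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def centred(self) -> "FeatureMatrix":
        """Return a copy with column means removed."""
        return FeatureMatrix(
            self.values - self.values.mean(axis=0, keepdims=True),
            list(self.feature_ids),
            list(self.sample_ids),
        )


@dataclass
class Outcome:
    """Outcome vector with a model-family tag.

    For ``survival`` the outcome carries event times and a 0/1 event
    indicator; for the other families ``values`` is the response itself.
    """

    family: str
    values: np.ndarray
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in OUTCOME_FAMILIES:
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "survival":
            if self.time is None or self.event is None:
                raise ValueError("survival outcome requires time and event vectors")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=float)
            if self.time.shape != self.event.shape or self.time.ndim != 1:
                raise ValueError("time and event must be matching 1-d vectors")
            if np.any(self.time <= 0):
                raise ValueError("survival times must be strictly positive")
            if not np.all(np.isin(self.event, (0.0, 1.0))):
                raise ValueError("event indicator must be 0/1")
            self.values = self.time
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 1:
                raise ValueError("outcome must be a 1-d vector")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("outcome contains non-finite values")
            if self.family == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError("binary outcome must take values in {0, 1}")
            if self.family == "count":
                if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                    raise ValueError("count outcome must be nonnegative integers")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, idx: np.ndarray) -> "Outcome":
        """Row-subset / reorder (used by the permutation shuffle)."""
        if self.family == "survival":
            return Outcome("survival", None, time=self.time[idx], event=self.event[idx])
        return Outcome(self.family, self.values[idx])


@dataclass
class CovariateMatrix:
    """n x P matrix of fixed-effect covariates (P may be zero)."""

    values: np.ndarray
    covariate_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("covariate matrix must be two-dimensional")
        self.covariate_ids = [str(c) for c in self.covariate_ids]
        if len(self.covariate_ids) != self.values.shape[1]:
            raise ValueError("covariate id count does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix contains non-finite values")

    @property
    def P(self) -> int:
        return self.values.shape[1]

    def take(self, idx: np.ndarray) -> "CovariateMatrix":
        return CovariateMatrix(self.values[idx], list(self.covariate_ids))


@dataclass
class PValueVector:
    """Per-feature two-sided p-values; failed fits are NaN and counted."""

    values: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = np.isfinite(self.values)
        if np.any((self.values[ok] < 0) | (self.values[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        self.n_failed = int(np.sum(~ok))

    def min_p(self) -> float:
        """Minimum over non-missing entries; error if every fit failed."""
        ok = np.isfinite(self.values)
        if not np.any(ok):
            raise ValueError("all model fits failed; no minimum p-value exists")
        return float(np.min(self.values[ok]))


@dataclass
class MinPNull:
    """The permutation null: K minimum p-values, one per shuffle replicate."""

    q: np.ndarray
    K: int = 0
    n_failed_total: int = 0
    M: int | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a nonempty 1-d vector")
        if np.any(self.q <= 0) or np.any(self.q > 1):
            raise ValueError("minimum p-values must lie in (0, 1]")
        self.K = int(self.q.size)


@dataclass
class ThresholdEstimate:
    """MWSL with confidence limits plus the derived ENT and R ratio.

    ENT = alpha / MWSL is the number of independent tests that a Bonferroni
    correction would need to reach the same threshold; R = 100 * ENT / M
    summarises redundancy among the M features.
    """

    mwsl: float
    mwsl_ci_low: float
    mwsl_ci_up: float
    alpha: float
    K: int
    M: int | None = None
    ent: float = field(init=False)
    ent_ci_low: float = field(init=False)
    ent_ci_up: float = field(init=False)
    r_ratio: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.mwsl <= 1):
            raise ValueError("MWSL must lie in (0, 1]")
        if not (self.mwsl_ci_low <= self.mwsl <= self.mwsl_ci_up):
            raise ValueError("MWSL must lie within its confidence limits")
        self.ent = self.alpha / self.mwsl
        self.ent_ci_low = self.alpha / self.mwsl_ci_up
        self.ent_ci_up = self.alpha / self.mwsl_ci_low
        self.r_ratio = 100.0 * self.ent / self.M if self.M else None

    def as_dict(self) -> dict:
        return {
            "mwsl": self.mwsl,
            "mwsl_ci_low": self.mwsl_ci_low,
            "mwsl_ci_up": self.mwsl_ci_up,
            "ent": self.ent,
            "ent_ci_low": self.ent_ci_low,
            "ent_ci_up": self.ent_ci_up,
            "r_ratio": self.r_ratio,
            "alpha": self.alpha,
            "K": self.K,
            "M": self.M,
        }
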