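"""Permutation-null and threshold-extraction checks against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mwsl.config import RunConfig
from mwsl.datatypes import Outcome
from mwsl.permutation import mwsl_from_null, permute_null, run_mwsl

from conftest import make_features


def test_uniform_grid_quantile():
    K = 1000
    q = np.arange(1, K + 1) / K
    est = mwsl_from_null(q, alpha=0.05, M=10)
    assert est.mwsl == pytest.approx(0.05)
    assert est.ent == pytest.approx(1.0)
    assert est.r_ratio == pytest.approx(10.0)


def test_confidence_interval_positions():
    # alpha=0.05, K=10000: centre 500, offset 0.95*sqrt(500*0.95)=20.7
    # -> order statistics 479 and 521
    K = 10_000
    q = np.arange(1, K + 1) / K  # value at rank i is i/K, so ranks are readable
    est = mwsl_from_null(q, alpha=0.05)
    assert est.mwsl == pytest.approx(500 / K)
    assert est.mwsl_ci_low == pytest.approx(479 / K)
    assert est.mwsl_ci_up == pytest.approx(521 / K)


def test_beta_null_reproduces_printed_threshold():
    """Beta(1,345) min-p nulls: MWSL near the analytic 1.4867e-4, ENT near 336.

    Averaged over independent nulls so the check compares against the
    Monte-Carlo standard error of the mean (rel. s.e. of one quantile is
    about 4.5% at K=10000; 6 replicates bring it below 2%).
    """
    ests = []
    for seed in range(6):
        q = np.random.default_rng(seed).beta(1.0, 345.0, size=10_000)
        ests.append(mwsl_from_null(q, alpha=0.05))
    analytic = 1.0 - 0.95 ** (1.0 / 345.0)
    mean_mwsl = np.mean([e.mwsl for e in ests])
    assert mean_mwsl == pytest.approx(analytic, rel=0.05)
    assert np.mean([e.ent for e in ests]) == pytest.approx(336, rel=0.05)


def test_alpha_quantile_unresolvable():
    with pytest.raises(ValueError, match="too small"):
        mwsl_from_null(np.array([0.2, 0.4, 0.9]), alpha=0.05)


def test_permutation_floor_enforced():
    X = make_features(300, 3, seed=1)
    y = Outcome("continuous", np.random.default_rng(0).standard_normal(300))
    with pytest.raises(ValueError, match="floor"):
        permute_null(y, X, K=100, seed=0)


def test_single_feature_null_is_uniform():
    rng = np.random.default_rng(4)
    n = 150
    X = rng.standard_normal((n, 1))
    y = Outcome("continuous", rng.standard_normal(n))
    null = permute_null(y, X, K=2000, seed=8)
    assert stats.kstest(null.q, "uniform").pvalue > 0.01


def test_identical_columns_reduce_to_single_test():
    rng = np.random.default_rng(4)
    n = 150
    x = rng.standard_normal(n)
    y = Outcome("continuous", rng.standard_normal(n))
    q1 = permute_null(y, x[:, None], K=200, seed=8).q
    q10 = permute_null(y, np.tile(x[:, None], (1, 10)), K=200, seed=8).q
    # identical up to BLAS summation order in the batched correlations
    np.testing.assert_allclose(q1, q10, rtol=1e-10)


def test_min_p_null_matches_beta_order_statistic():
    rng = np.random.default_rng(21)
    n, M = 200, 20
    X = rng.standard_normal((n, M))
    y = Outcome("continuous", rng.standard_normal(n))
    null = permute_null(y, X, K=2000, seed=13)
    assert stats.kstest(null.q, stats.beta(1, M).cdf).pvalue > 0.01


def test_independent_features_ent_near_M():
    rng = np.random.default_rng(2)
    n, M = 400, 100
    X = make_features(n, M, seed=2)
    y = Outcome("continuous", rng.standard_normal(n))
    res = run_mwsl(y, X, None, RunConfig(K=2000, seed=3))
    analytic = 1.0 - 0.95 ** (1.0 / M)
    assert res.threshold.mwsl == pytest.approx(analytic, rel=0.25)
    assert res.threshold.ent == pytest.approx(M, rel=0.15)


def test_identical_features_ent_near_one():
    rng = np.random.default_rng(6)
    n = 300
    x = rng.standard_normal(n)
    X = np.tile(x[:, None], (1, 20))
    from mwsl.datatypes import FeatureMatrix

    fm = FeatureMatrix(X, [f"f{j}" for j in range(20)], [f"s{i}" for i in range(n)])
    y = Outcome("continuous", rng.standard_normal(n))
    res = run_mwsl(y, fm, None, RunConfig(K=2000, seed=9))
    assert res.threshold.mwsl == pytest.approx(0.05, rel=0.25)
    assert res.threshold.ent == pytest.approx(1.0, rel=0.25)


def test_ent_decreases_with_correlation():
    from mwsl.synthetic import CorrelationBand, gen_correlated_features

    n, M = 400, 50
    y = Outcome("continuous", np.random.default_rng(14).standard_normal(n))
    ents = {}
    for rho in (0.3, 0.7):
        X = gen_correlated_features(M, n, CorrelationBand(rho - 0.05, rho + 0.05), seed=15)
        ents[rho] = run_mwsl(y, X, None, RunConfig(K=1000, seed=16)).threshold.ent
    assert ents[0.7] < ents[0.3]


def test_mwsl_bounds_and_ci_ordering():
    rng = np.random.default_rng(31)
    n, M = 200, 30
    X = make_features(n, M, seed=31)
    y = Outcome("continuous", rng.standard_normal(n))
    for K in (1000, 10_000):
        res = run_mwsl(y, X, None, RunConfig(K=K, seed=17))
        t = res.threshold
        assert t.mwsl_ci_low <= t.mwsl <= t.mwsl_ci_up
        assert 0.05 / M * 0.2 <= t.mwsl <= 0.05 * 1.5  # alpha/M <= MWSL <= alpha, with slack
        assert 0.5 <= t.ent <= 1.5 * M
    # CI width shrinks (relatively) as K grows
    w = {}
    for K in (1000, 10_000):
        t = run_mwsl(y, X, None, RunConfig(K=K, seed=18)).threshold
        w[K] = (t.mwsl_ci_up - t.mwsl_ci_low) / t.mwsl
    assert w[10_000] < w[1000]


def test_seed_reproducibility_and_order_independence():
    rng = np.random.default_rng(1)
    n = 120
    X = make_features(n, 5, seed=1)
    y = Outcome("continuous", rng.standard_normal(n))
    a = permute_null(y, X, K=150, seed=99).q
    b = permute_null(y, X, K=150, seed=99).q
    np.testing.assert_array_equal(a, b)
    # first replicates of a longer run match a shorter run up to the spawn count
    c = permute_null(y, X, K=100, seed=99).q
    np.testing.assert_array_equal(a[:100], c)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    K=st.integers(min_value=200, max_value=3000),
    alpha=st.floats(min_value=0.01, max_value=0.2),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_threshold_invariants_property(K, alpha, seed):
    """For any null vector: CI ordering, ENT identity, and quantile bounds."""
    gen = np.random.default_rng(seed)
    q = gen.uniform(1e-12, 1.0, size=K)
    if round(alpha * K) < 1:
        return
    est = mwsl_from_null(q, alpha=alpha, M=7)
    assert est.mwsl_ci_low <= est.mwsl <= est.mwsl_ci_up
    assert est.ent == pytest.approx(alpha / est.mwsl)
    assert est.ent_ci_low == pytest.approx(alpha / est.mwsl_ci_up)
    assert q.min() <= est.mwsl <= q.max()


def test_correlated_outcome_does_not_shift_ent():
    """Coupling the outcome to the features leaves the permutation ENT
    unchanged within confidence limits: the shuffle breaks the coupling, so
    only the feature correlation structure matters."""
    from mwsl.synthetic import CorrelationBand, OutcomeSpec, gen_correlated_features, gen_outcome

    n, M, K = 500, 50, 1000
    X = gen_correlated_features(M, n, CorrelationBand(0.45, 0.55), seed=61)
    y_null = gen_outcome(OutcomeSpec(family="continuous"), n=n, seed=62)
    y_link = gen_outcome(
        OutcomeSpec(family="continuous", linkage="linear", weights={0: 1.0, 10: 1.0, 20: 1.0}, noise_sd=2.0),
        X=X, seed=63,
    )
    t_null = run_mwsl(y_null, X, None, RunConfig(K=K, seed=64)).threshold
    t_link = run_mwsl(y_link, X, None, RunConfig(K=K, seed=65)).threshold
    assert t_null.ent_ci_low <= t_link.ent_ci_up and t_link.ent_ci_low <= t_null.ent_ci_up
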