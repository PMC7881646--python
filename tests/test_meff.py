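"""Closed-form Meff estimators against hand-computed and analytic spectra."""

import numpy as np
import pytest

from mwsl.meff import (
    all_meff,
    beta_approx_mwsl,
    bonferroni_mwsl,
    eigen_spectrum,
    EigenSpectrum,
    meff_alternatives,
    meff_mwsl,
)

from conftest import make_features


def equicorr_spectrum(M: int, rho: float) -> EigenSpectrum:
    """Population spectrum of compound symmetry: 1+(M-1)rho, then (1-rho)s."""
    lam = np.r_[1 + (M - 1) * rho, np.full(M - 1, 1 - rho)]
    return EigenSpectrum(lam, M, M)


def test_identity_spectrum():
    spec = eigen_spectrum(np.eye(5), is_correlation=True)
    np.testing.assert_allclose(spec.lambdas, np.ones(5))
    assert spec.rank == 5


def test_identical_features_spectrum():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    X = np.tile(x[:, None], (1, 6))
    spec = eigen_spectrum(X)
    np.testing.assert_allclose(spec.lambdas, np.r_[6.0, np.zeros(5)], atol=1e-8)
    assert spec.rank == 1


def test_two_by_two_spectrum():
    R = np.array([[1.0, 0.6], [0.6, 1.0]])
    spec = eigen_spectrum(R)
    np.testing.assert_allclose(spec.lambdas, [1.6, 0.4])


def test_nonsymmetric_rejected():
    R = np.array([[1.0, 0.6], [0.1, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        eigen_spectrum(R, is_correlation=True)


def test_trace_rule_enforced():
    with pytest.raises(ValueError, match="trace"):
        EigenSpectrum(np.array([2.0, 0.5]), 2, 2)


def test_meff_mwsl_hand_computed():
    # spectrum (2, 0): ((sqrt2)/ln2)^2 / (2/2 + sqrt2) = 4.1628/2.4142
    spec = EigenSpectrum(np.array([2.0, 0.0]), 2, 1)
    expected = (np.sqrt(2) / np.log(2)) ** 2 / (1.0 + np.sqrt(2))
    est = meff_mwsl(spec)
    assert est.value == pytest.approx(expected, rel=1e-12)
    assert est.value == pytest.approx(1.724, abs=5e-4)


def test_meff_mwsl_domain_error_at_identity():
    spec = EigenSpectrum(np.ones(4), 4, 4)
    with pytest.raises(ValueError, match="lambda_1 > 1"):
        meff_mwsl(spec)


def test_meff_mwsl_equicorrelated_650():
    est = meff_mwsl(equicorr_spectrum(650, 0.7))
    assert est.value == pytest.approx(166.5, abs=0.5)


def test_alternatives_identity_limit():
    spec = EigenSpectrum(np.ones(9), 9, 9)
    for m in ("nyholt", "liji", "galwey"):
        assert meff_alternatives(spec, m).value == pytest.approx(9.0)
    assert meff_alternatives(spec, "gao").value == np.ceil(0.995 * 9)


def test_alternatives_fully_correlated_limit():
    M = 9
    spec = EigenSpectrum(np.r_[float(M), np.zeros(M - 1)], M, 1)
    for m in ("nyholt", "liji", "gao", "galwey"):
        assert meff_alternatives(spec, m).value == pytest.approx(1.0)


def test_nyholt_population_value_weak_correlation():
    est = meff_alternatives(equicorr_spectrum(650, 0.125), "nyholt")
    assert est.value == pytest.approx(640, abs=1)


def test_nyholt_variance_convention_option():
    M = 5
    spec = EigenSpectrum(np.r_[float(M), np.zeros(M - 1)], M, 1)
    sample = meff_alternatives(spec, "nyholt").value
    pop = meff_alternatives(spec, "nyholt", nyholt_variance="population").value
    assert sample == pytest.approx(1.0)
    assert pop > sample  # population variance is smaller, so Meff is larger


def test_liji_canonical_differs_on_fractional_spectra():
    spec = equicorr_spectrum(4, 0.5)  # lambdas 2.5, 0.5, 0.5, 0.5
    described = meff_alternatives(spec, "liji").value  # 1 + 3*0.5 = 2.5
    canonical = meff_alternatives(spec, "liji_canonical").value  # 1.5 + 3*0.5 = 3.0
    assert described == pytest.approx(2.5)
    assert canonical == pytest.approx(3.0)


def test_monotone_in_correlation():
    rhos = np.arange(0.1, 0.95, 0.1)
    M = 60
    for method in ("mwsl", "nyholt", "liji", "gao", "galwey"):
        vals = []
        for rho in rhos:
            spec = equicorr_spectrum(M, rho)
            if method == "mwsl":
                vals.append(meff_mwsl(spec).value)
            else:
                vals.append(meff_alternatives(spec, method).value)
        diffs = np.diff(vals)
        assert np.all(diffs <= 1e-9), f"{method} not non-increasing in rho: {vals}"


def test_gao_fraction_behaviour():
    spec = equicorr_spectrum(10, 0.5)
    k_small = meff_alternatives(spec, "gao", gao_fraction=0.5).value
    k_large = meff_alternatives(spec, "gao", gao_fraction=0.995).value
    assert k_small <= k_large


def test_rank_deficient_spectrum_handled():
    X = make_features(20, 50, seed=3)  # n-1 < M: zero eigenvalues appear
    spec = eigen_spectrum(X)
    assert spec.rank <= 19
    est = meff_mwsl(spec)
    assert 1 <= est.value <= 50


def test_beta_approx_meff_one_is_uniform():
    est = beta_approx_mwsl(1.0, alpha=0.05, K=10_000, seed=4, mode="sample")
    assert est.mwsl == pytest.approx(0.05, rel=0.15)


@pytest.mark.parametrize("meff,ent_printed", [(345, 336), (1931, 1883), (11570, 11279)])
def test_beta_approx_printed_ents(meff, ent_printed):
    analytic = beta_approx_mwsl(meff, alpha=0.05, K=10_000, mode="analytic")
    assert analytic.ent == pytest.approx(0.05 / (1 - 0.95 ** (1 / meff)), rel=1e-9)
    assert analytic.ent == pytest.approx(ent_printed, rel=0.005)


@pytest.mark.parametrize("meff", [2.0, 50.0, 1000.0])
def test_sample_and_analytic_modes_agree(meff):
    """Sampled Beta(1, Meff) thresholds are unbiased for the analytic quantile.

    Averaged over independent runs and compared within twice the
    Monte-Carlo standard error of the mean.
    """
    K = 10_000
    reps = 8
    sampled = np.mean(
        [beta_approx_mwsl(meff, K=K, seed=s, mode="sample").mwsl for s in range(reps)]
    )
    analytic = beta_approx_mwsl(meff, K=K, mode="analytic")
    alpha = 0.05
    from scipy import stats

    f = stats.beta(1, meff).pdf(analytic.mwsl)
    se = np.sqrt(alpha * (1 - alpha) / K) / f / np.sqrt(reps)
    assert abs(sampled - analytic.mwsl) < 2 * se


def test_bonferroni_shortcut():
    assert bonferroni_mwsl(345, 0.05) == pytest.approx(0.05 / 345)
    with pytest.raises(ValueError):
        bonferroni_mwsl(0.5)
    with pytest.raises(ValueError):
        beta_approx_mwsl(0.5)


def test_all_meff_skips_mwsl_on_identity():
    ests = all_meff(EigenSpectrum(np.ones(5), 5, 5))
    assert "mwsl" not in ests
    assert set(ests) == {"nyholt", "liji", "gao", "galwey"}
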