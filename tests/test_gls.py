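import numpy as np
import pytest

from pglspatial.covariance import VarianceParams, combined_variance
from pglspatial.gls import (
    _aicc,
    dependence_tests,
    fit_pgls_spatial,
    gls_fit_fixed,
    gls_r_squared,
    pagel_lambda_signal,
)
from pglspatial.simulate import SimulationTruth, simulate_outcome


def _design(n, rng, p=2):
    return np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])


def test_gls_with_identity_variance_equals_ols(rng):
    n = 30
    X = _design(n, rng, p=3)
    y = X @ [1.0, 2.0, -1.0] + rng.normal(size=n)
    fit = gls_fit_fixed(X, y, np.eye(n))
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = resid @ resid / n
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + n)
    np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-12)
    assert fit.sigma2 == pytest.approx(s2, rel=1e-12)
    assert fit.loglik == pytest.approx(ll, rel=1e-12)


def test_perfect_fit_flagged_degenerate(rng):
    n = 20
    X = _design(n, rng)
    y = X @ [1.0, 2.0]
    fit = gls_fit_fixed(X, y, np.eye(n))
    assert fit.degenerate
    assert not np.isfinite(fit.aicc)


def test_aicc_formula():
    assert _aicc(loglik=-5.0, k=3, n=10) == pytest.approx(20.0)
    assert not np.isfinite(_aicc(loglik=-5.0, k=9, n=10))
    # correction vanishes for large n
    assert _aicc(-5.0, 3, 10**5) - (-2 * -5.0 + 2 * 3) < 1e-3


def test_rank_deficient_design_raises(toy_cov, rng):
    n = toy_cov.n
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
        gls_fit_fixed(X, rng.normal(size=n), np.eye(n))


def test_mode_neither_equals_fixed_fit(toy_cov, rng):
    n = toy_cov.n
    X = _design(n, rng)
    y = rng.normal(size=n)
    a = fit_pgls_spatial(X, y, toy_cov, mode="neither")
    b = gls_fit_fixed(X, y, np.diag(toy_cov.h))
    np.testing.assert_allclose(a.beta, b.beta, rtol=1e-10)
    assert a.loglik == pytest.approx(b.loglik)
    assert a.params.lam == 0.0 and a.params.phi == 0.0


def test_nesting_of_dependence_models(toy_cov, rng):
    n = toy_cov.n
    X = _design(n, rng)
    truth = SimulationTruth(0.5, 0.3, 1.0, {"a": 0.0, "b": 1.0}, None, 0)
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    tests = dependence_tests(X, y, toy_cov)
    full = tests.fits["both"].loglik
    for mode in ("lambda_only", "phi_only", "neither"):
        assert full >= tests.fits[mode].loglik - 1e-6
    assert 0 <= tests.p_lambda <= 1 and 0 <= tests.p_phi <= 1


def test_null_simulation_keeps_estimates_small(toy_cov, rng):
    """iid data: median lambda-hat and phi-hat stay near zero."""
    n = toy_cov.n
    lams, phis = [], []
    for _ in range(20):
        X = _design(n, rng)
        y = rng.normal(size=n)
        fit = fit_pgls_spatial(X, y, toy_cov, mode="both")
        lams.append(fit.params.lam)
        phis.append(fit.params.phi)
    assert np.median(lams) < 0.15
    assert np.median(phis) < 0.15


def test_phi_lrt_detects_strong_spatial_dependence(toy_cov, rng):
    """Power check: phi = 0.8 structure is detected in the large majority of draws."""
    truth = SimulationTruth(0.0, 0.8, 1.0, {"i": 0.0}, None, 0)
    X = np.ones((toy_cov.n, 1))
    hits = 0
    n_reps = 25
    for _ in range(n_reps):
        y = simulate_outcome(X, truth, toy_cov, seed=rng)
        hits += dependence_tests(X, y, toy_cov).p_phi < 0.05
    assert hits / n_reps >= 0.8


def test_likelihood_invariant_under_permutation(toy_cov, rng):
    n = toy_cov.n
    X = _design(n, rng)
    truth = SimulationTruth(0.6, 0.2, 1.0, {"a": 0.5, "b": 1.0}, None, 0)
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    fit = fit_pgls_spatial(X, y, toy_cov, mode="both")
    perm = rng.permutation(n)
    fit_p = fit_pgls_spatial(X[perm], y[perm], toy_cov.subset(perm), mode="both")
    assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-5)
    assert fit_p.params.lam == pytest.approx(fit.params.lam, abs=1e-3)


def test_response_scaling_equivariance(toy_cov, rng):
    n = toy_cov.n
    X = _design(n, rng)
    truth = SimulationTruth(0.5, 0.2, 1.0, {"a": 0.5, "b": 1.0}, None, 0)
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    c = 3.7
    f1 = fit_pgls_spatial(X, y, toy_cov, mode="both")
    f2 = fit_pgls_spatial(X, c * y, toy_cov, mode="both")
    np.testing.assert_allclose(f2.beta, c * f1.beta, rtol=1e-4)
    assert np.sqrt(f2.sigma2) == pytest.approx(c * np.sqrt(f1.sigma2), rel=1e-4)
    assert f2.params.lam == pytest.approx(f1.params.lam, abs=1e-3)
    assert f2.params.phi == pytest.approx(f1.params.phi, abs=1e-3)
    r1 = gls_r_squared(f1, X, y, toy_cov)
    r2 = gls_r_squared(f2, X, c * y, toy_cov)
    assert r2 == pytest.approx(r1, abs=1e-4)


def test_pagel_lambda_at_zero_equals_ols_likelihood(toy_cov, rng):
    y = rng.normal(size=toy_cov.n)
    res = pagel_lambda_signal(y, toy_cov.sigma, toy_cov.h)
    n = toy_cov.n
    s2 = np.var(y)
    ll_ols = -0.5 * (n * np.log(2 * np.pi * s2) + n)
    if res.lam_hat == 0.0:
        assert res.loglik_hat == pytest.approx(ll_ols, rel=1e-8)
    else:
        assert res.loglik_hat >= ll_ols - 1e-8


def test_pagel_lambda_requires_variation(toy_cov):
    with pytest.raises(ValueError, match="constant"):
        pagel_lambda_signal(np.ones(toy_cov.n), toy_cov.sigma, toy_cov.h)


def test_r2_zero_for_intercept_only(toy_cov, rng):
    truth = SimulationTruth(0.4, 0.2, 1.0, {"intercept": 1.0}, None, 0)
    X = np.ones((toy_cov.n, 1))
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    fit = fit_pgls_spatial(X, y, toy_cov, mode="both")
    assert gls_r_squared(fit, X, y, toy_cov) == pytest.approx(0.0, abs=1e-10)


def test_r2_one_for_perfect_fit(toy_cov, rng):
    X = _design(toy_cov.n, rng)
    y = X @ [1.0, 2.0]
    fit = fit_pgls_spatial(X, y, toy_cov, mode="both")
    assert gls_r_squared(fit, X, y, toy_cov) == pytest.approx(1.0)


def test_r2_large_for_strong_effect(toy_cov, rng):
    X = _design(toy_cov.n, rng)
    truth = SimulationTruth(0.0, 0.0, 0.25, {"a": 0.0, "b": 2.0}, None, 0)
    y = simulate_outcome(X, truth, toy_cov, seed=rng)
    fit = fit_pgls_spatial(X, y, toy_cov, mode="both")
    assert gls_r_squared(fit, X, y, toy_cov) > 0.5
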