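"""L1-penalized probit: oracle equivalence, KKT conditions, cross-validation."""

from __future__ import annotations

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import ndtri

from volunteerbias.probit import (
    cross_validate_lambda,
    fit_penalized_probit,
    lambda_grid,
    lambda_max,
    negloglik,
    predict_probability,
)


def simulate_probit(n=800, k=6, seed=0, beta_scale=0.7):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, k)) < 0.4).astype(float)
    beta = beta_scale * np.array([1.0, -1.0, 0.5, 0.0, 0.0, 0.0])[:k]
    eta = -0.3 + X @ beta
    s = (rng.standard_normal(n) < eta).astype(float)
    return X, s, beta


def test_unpenalized_fit_matches_newton_mle_oracle():
    """lambda = 0 must reproduce the unpenalized probit MLE computed by an
    independent Newton solver."""
    X, s, _ = simulate_probit()
    ours = fit_penalized_probit(X, s, lam=0.0, max_iter=20_000, tol=1e-9)
    ref = sm.Probit(s, sm.add_constant(X)).fit(disp=0)
    assert abs(ours.intercept - ref.params[0]) < 1e-4 * max(1, abs(ref.params[0]))
    assert np.allclose(ours.coef, ref.params[1:], rtol=1e-4, atol=1e-5)


def test_lambda_max_is_the_kkt_entry_point():
    X, s, _ = simulate_probit(seed=3)
    lmax = lambda_max(X, s)
    above = fit_penalized_probit(X, s, lam=lmax * 1.01)
    assert above.n_selected == 0
    # the intercept-only optimum is Phi^{-1}(mean)
    assert abs(above.intercept - ndtri(s.mean())) < 1e-5
    below = fit_penalized_probit(X, s, lam=lmax * 0.8)
    assert below.n_selected >= 1


def test_heavier_penalty_selects_fewer_columns():
    X, s, _ = simulate_probit(seed=4)
    lmax = lambda_max(X, s)
    sizes = [
        fit_penalized_probit(X, s, lam=lam).n_selected
        for lam in lambda_grid(lmax, n_points=6)
    ]
    assert sizes == sorted(sizes)
    assert sizes[-1] > sizes[0]


def test_solution_satisfies_kkt_conditions():
    X, s, _ = simulate_probit(seed=5)
    lam = 0.05
    fit = fit_penalized_probit(X, s, lam=lam, tol=1e-8)
    assert fit.converged
    assert fit.kkt_norm < 1e-6


def test_penalized_deviance_not_below_mle_deviance():
    X, s, _ = simulate_probit(seed=6)
    mle = fit_penalized_probit(X, s, lam=0.0, max_iter=20_000, tol=1e-9)
    pen = fit_penalized_probit(X, s, lam=0.05)

    def dev(fit):
        return negloglik(fit.intercept + X @ fit.coef, s)

    assert dev(pen) >= dev(mle) - 1e-10


def test_cross_validation_recovers_true_support():
    X, s, beta = simulate_probit(n=4000, seed=7)
    cv = cross_validate_lambda(X, s, folds=5, seed=1, refit_active_set=False)
    active = set(np.nonzero(cv.fit.coef)[0])
    assert set(np.nonzero(beta)[0]) <= active
    # the final path is fitted down to the chosen penalty
    best = int(np.argmin(cv.cv_deviance))
    assert cv.chosen_lambda == cv.lambda_grid[best]
    assert len(cv.path) == best + 1
    assert cv.path[-1].lambda_ == cv.chosen_lambda


def test_cross_validation_is_deterministic():
    X, s, _ = simulate_probit(n=1200, seed=8)
    a = cross_validate_lambda(X, s, folds=4, seed=2)
    b = cross_validate_lambda(X, s, folds=4, seed=2)
    assert a.chosen_lambda == b.chosen_lambda
    assert np.array_equal(a.fit.coef, b.fit.coef)
    assert np.array_equal(a.cv_deviance, b.cv_deviance)


def test_post_lasso_refit_removes_shrinkage():
    """Refitting the CV-selected active set without penalty must match the
    Newton MLE on those columns."""
    X, s, _ = simulate_probit(n=2500, seed=9)
    cv = cross_validate_lambda(X, s, folds=4, seed=3, refit_active_set=True)
    active = [i for i, c in enumerate(cv.fit.coef) if c != 0.0]
    ref = sm.Probit(s, sm.add_constant(X[:, active])).fit(disp=0)
    assert abs(cv.fit.intercept - ref.params[0]) < 1e-3
    assert np.allclose(
        np.asarray(cv.fit.coef)[active], ref.params[1:], rtol=1e-3, atol=1e-4
    )


def test_predict_probability_matches_probit_cdf_and_clips():
    X, s, _ = simulate_probit(seed=10)
    fit = fit_penalized_probit(X, s, lam=0.02)
    pi, n_clipped = predict_probability(fit, X)
    from scipy.stats import norm

    expected = norm.cdf(fit.intercept + X @ fit.coef)
    assert np.allclose(pi, np.clip(expected, 1e-8, 1 - 1e-8))
    assert n_clipped == int(
        ((expected < 1e-8) | (expected > 1 - 1e-8)).sum()
    )


def test_separation_is_flagged():
    # perfectly separated data at lambda = 0
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    s = np.array([0.0, 0.0, 1.0, 1.0])
    with pytest.warns(UserWarning):
        fit = fit_penalized_probit(X, s, lam=0.0, max_iter=5000)
    assert fit.separation_suspected
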