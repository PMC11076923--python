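"""Weighted inference: sandwich-oracle equivalence, Z tests, bias reduction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from volunteerbias.inference import (
    bias_reduction,
    compare_associations,
    fit_bivariate_lpm,
    fit_standardized_linear,
    run_association_batch,
    weighted_mean,
    weighted_sd,
)
from volunteerbias.weights import WeightSet


def hc1_matrix_oracle(y, x, w):
    """Brute-force weighted LPM slope and HC1 sandwich SE.

    bread = (X'WX)^-1, meat = sum_i w_i^2 e_i^2 x_i x_i', scale n/(n-2).
    """
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    bread = np.linalg.inv(X.T @ W @ X)
    beta = bread @ X.T @ W @ y
    e = y - X @ beta
    meat = X.T @ np.diag(w**2 * e**2) @ X
    cov = bread @ meat @ bread * len(y) / (len(y) - 2)
    return beta[1], np.sqrt(cov[1, 1])


FIXTURE_Y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
FIXTURE_X = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
FIXTURE_W = np.array([0.5, 1.5, 1.0, 2.0, 0.7, 0.3])


def test_weighted_lpm_matches_matrix_oracle_to_1e10():
    est = fit_bivariate_lpm(FIXTURE_Y, FIXTURE_X, FIXTURE_W)
    beta, se = hc1_matrix_oracle(FIXTURE_Y, FIXTURE_X, FIXTURE_W)
    assert abs(est.beta - beta) < 1e-10
    assert abs(est.robust_se - se) < 1e-10


def test_unweighted_lpm_matches_matrix_oracle_to_1e10():
    est = fit_bivariate_lpm(FIXTURE_Y, FIXTURE_X)
    beta, se = hc1_matrix_oracle(FIXTURE_Y, FIXTURE_X, np.ones(6))
    assert abs(est.beta - beta) < 1e-10
    assert abs(est.robust_se - se) < 1e-10


def test_uniform_weights_reduce_to_unweighted():
    rng = np.random.default_rng(1)
    y = rng.random(50)
    x = (rng.random(50) < 0.5).astype(float)
    a = fit_bivariate_lpm(y, x)
    b = fit_bivariate_lpm(y, x, np.full(50, 3.7))
    assert abs(a.beta - b.beta) < 1e-12
    assert abs(a.robust_se - b.robust_se) < 1e-10


def test_lpm_drops_incomplete_rows():
    y = np.array([1.0, np.nan, 0.0, 1.0, 0.0])
    x = np.array([1.0, 1.0, np.nan, 0.0, 1.0])
    est = fit_bivariate_lpm(y, x)
    assert est.n_used == 3


def test_constant_exposure_raises():
    with pytest.raises(ValueError):
        fit_bivariate_lpm(np.array([0.0, 1.0, 0.0]), np.ones(3))


def test_weighted_mean_and_sd_match_numpy_under_uniform_weights():
    rng = np.random.default_rng(2)
    x = rng.random(40)
    assert abs(weighted_mean(x, np.full(40, 2.0)) - x.mean()) < 1e-12
    assert abs(weighted_sd(x, np.full(40, 2.0)) - x.std(ddof=1)) < 1e-12


def test_standardized_slope_is_pearson_correlation_unweighted():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(300)
    y = 0.5 * x + rng.standard_normal(300)
    est = fit_standardized_linear(y, x)
    r = np.corrcoef(y, x)[0, 1]
    assert abs(est.beta - r) < 1e-10


def test_z_statistic_and_p_value_match_normal_oracle():
    a = fit_bivariate_lpm(FIXTURE_Y, FIXTURE_X, outcome="y", exposure="x")
    y2 = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    b = fit_bivariate_lpm(y2, FIXTURE_X, outcome="y", exposure="x")
    cmp_ = compare_associations(a, b)
    z = (a.beta - b.beta) / np.hypot(a.robust_se, b.robust_se)
    assert abs(cmp_.z - z) < 1e-12
    assert abs(cmp_.p_two_sided - 2 * stats.norm.sf(abs(z))) < 1e-12


def test_compare_associations_requires_same_pair():
    a = fit_bivariate_lpm(FIXTURE_Y, FIXTURE_X, outcome="u", exposure="x")
    b = fit_bivariate_lpm(FIXTURE_Y, FIXTURE_X, outcome="v", exposure="x")
    with pytest.raises(ValueError):
        compare_associations(a, b)


def test_bias_reduction_values():
    assert abs(bias_reduction(ref=1.0, unweighted=0.0, weighted=1.0) - 1.0) < 1e-12
    assert abs(bias_reduction(ref=1.0, unweighted=0.0, weighted=0.5) - 0.5) < 1e-12
    # weighting that overshoots past the reference still counts distance
    assert abs(bias_reduction(ref=1.0, unweighted=0.0, weighted=1.5) - 0.5) < 1e-12
    # moving away from the reference is negative
    assert bias_reduction(ref=1.0, unweighted=0.5, weighted=0.0) < 0


def test_bias_reduction_undefined_when_no_bias():
    with pytest.raises(ValueError):
        bias_reduction(ref=1.0, unweighted=1.0, weighted=0.9)


def test_association_batch_shapes_and_definedness(tiny_codebook):
    rng = np.random.default_rng(4)
    n = 400
    def sample(p_poor):
        return pd.DataFrame(
            {
                "person_id": np.arange(n),
                "age_band": rng.choice(["40-49", "60-69"], n),
                "health": rng.choice(["poor", "good"], n, p=[p_poor, 1 - p_poor]),
                "tenure": rng.choice(["renter", "owner"], n),
                "region": ["eligible"] * n,
            }
        )

    cohort, reference = sample(0.2), sample(0.4)
    weights = WeightSet(
        person_id=np.arange(n),
        weight=np.ones(n),
        normalization="mean-one",
    )
    pairs = [
        {"outcome": "health=poor", "exposure": "tenure=owner", "kind": "lpm"},
        {"outcome": "health", "exposure": "age_band", "kind": "standardized"},
    ]
    batch = run_association_batch(cohort, reference, pairs, weights, tiny_codebook)
    assert len(batch) == 2
    for col in ("beta_reference", "beta_unweighted", "beta_weighted",
                "z_vs_reference", "bias_reduction", "bias_defined"):
        assert col in batch.columns
    # uniform weights: weighted equals unweighted
    assert np.allclose(batch["beta_weighted"], batch["beta_unweighted"])
    # independent noise: nothing should clear the |z| > 4 definedness bar
    assert not batch["bias_defined"].any()
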