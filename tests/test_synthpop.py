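"""Synthetic population generator: marginals, copula joints, selection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from volunteerbias.synthpop import (
    PopulationSpec,
    SelectionSpec,
    draw_reference_sample,
    draw_volunteers,
    generate_population,
    inject_missingness,
    selection_index,
    solve_intercept,
    stream_rng,
)


def test_marginals_match_specification(tiny_spec, tiny_population):
    n = len(tiny_population)
    for name, levels, probs in tiny_spec.variables:
        for level, p in zip(levels, probs):
            phat = (tiny_population[name] == level).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 5 * se, (name, level, phat, p)


def test_joint_cell_matches_gaussian_orthant_oracle(tiny_spec, tiny_population):
    """P(later level of A and later level of B) equals the bivariate-normal
    orthant probability implied by the copula — an oracle independent of the
    generator's sampling path."""
    rho = tiny_spec.latent_correlation[1, 2]  # health vs tenure
    c_health = stats.norm.ppf(0.3)   # P(health=poor) = 0.3
    c_tenure = stats.norm.ppf(0.35)  # P(tenure=renter) = 0.35
    mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    # P(Z_h > c_h, Z_t > c_t) = P(good, owner) by symmetry of -Z
    p_oracle = float(mvn.cdf([-c_health, -c_tenure]))
    joint = (
        (tiny_population["health"] == "good")
        & (tiny_population["tenure"] == "owner")
    ).mean()
    se = np.sqrt(p_oracle * (1 - p_oracle) / len(tiny_population))
    assert abs(joint - p_oracle) < 5 * se


def test_generation_is_deterministic(tiny_spec):
    a = generate_population(tiny_spec)
    b = generate_population(tiny_spec)
    assert a.equals(b)


def test_different_seeds_differ(tiny_spec):
    from dataclasses import replace

    b = generate_population(replace(tiny_spec, seed=tiny_spec.seed + 1))
    a = generate_population(tiny_spec)
    assert not a.drop(columns="person_id").equals(b.drop(columns="person_id"))


def test_stream_rng_streams_are_independent():
    a = stream_rng(3, "population").standard_normal(5)
    b = stream_rng(3, "selection").standard_normal(5)
    a2 = stream_rng(3, "population").standard_normal(5)
    assert np.allclose(a, a2)
    assert not np.allclose(a, b)


def test_non_psd_correlation_raises(tiny_spec):
    from dataclasses import replace

    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = 0.9
    corr[0, 2] = corr[2, 0] = 0.9
    corr[1, 2] = corr[2, 1] = -0.9
    with pytest.raises(ValueError, match="smallest eigenvalue"):
        generate_population(replace(tiny_spec, latent_correlation=corr))


def test_marginal_probabilities_must_sum_to_one():
    with pytest.raises(ValueError):
        PopulationSpec(
            n_population=100,
            variables=[("x", ("a", "b"), (0.6, 0.6))],
            latent_correlation=np.eye(1),
            seed=0,
        )


def test_solve_intercept_hits_target_rate(tiny_population, tiny_selection):
    eta = selection_index(tiny_population, tiny_selection)
    c = solve_intercept(eta, tiny_selection)
    realized = stats.norm.cdf(c + eta).mean()
    assert abs(realized - tiny_selection.target_rate) < 1e-6


def test_draw_volunteers_rate_and_true_prob(tiny_population, tiny_selection):
    cohort = draw_volunteers(tiny_population, tiny_selection)
    n = len(tiny_population)
    rate = len(cohort) / n
    se = np.sqrt(0.25 * 0.75 / n)
    assert abs(rate - 0.25) < 5 * se
    assert (cohort["source"] == "cohort").all()
    assert cohort["true_prob"].between(0, 1, inclusive="neither").all()
    # participation must lean toward the positively selected level
    p_good_cohort = (cohort["health"] == "good").mean()
    p_good_pop = (tiny_population["health"] == "good").mean()
    assert p_good_cohort > p_good_pop


def test_draw_volunteers_deterministic(tiny_population, tiny_selection):
    a = draw_volunteers(tiny_population, tiny_selection)
    b = draw_volunteers(tiny_population, tiny_selection)
    assert a.equals(b)


def test_reference_sample_size_and_source(tiny_population):
    ref = draw_reference_sample(
        tiny_population, sampling_fraction=0.10, response_rate=0.9, seed=2
    )
    n = len(tiny_population)
    expected = 0.09 * n
    assert abs(len(ref) - expected) < 5 * np.sqrt(expected)
    assert (ref["source"] == "reference").all()
    assert "true_prob" not in ref.columns


def test_reference_sample_refuses_tiny_expected_size(tiny_population):
    with pytest.raises(ValueError):
        draw_reference_sample(
            tiny_population, sampling_fraction=0.001, response_rate=0.5, seed=0
        )


def test_inject_missingness_rates_and_determinism(tiny_population):
    rates = {"health": 0.1, "tenure": 0.05}
    out = inject_missingness(tiny_population, rates, seed=4)
    n = len(out)
    for var, rate in rates.items():
        frac = out[var].isna().mean()
        assert abs(frac - rate) < 5 * np.sqrt(rate * (1 - rate) / n)
    out2 = inject_missingness(tiny_population, rates, seed=4)
    assert out["health"].isna().equals(out2["health"].isna())
    # untouched variables stay complete
    assert out["age_band"].notna().all()


def test_selection_spec_rejects_bad_rate():
    with pytest.raises(ValueError):
        SelectionSpec(coefficients={}, target_rate=1.5, seed=0)
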