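"""Two-species co-occurrence model: state probabilities, likelihood, MLE."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from occumeta.multi import (
    MultiModelSpec,
    StateProbs,
    conditional_occupancy,
    fit_multi,
    multi_site_log_likelihood,
    parse_multi_spec,
    predict_conditional_curves,
    state_probs,
)
from occumeta.simulate import SimulationConfig, simulate_multi
from occumeta.single import fit as fit_single


def test_state_probs_uniform_and_weighted():
    assert state_probs(0, 0, 0).as_array() == pytest.approx([0.25] * 4)
    s = state_probs(0, 0, np.log(3))
    assert s.as_array() == pytest.approx([1 / 6, 1 / 6, 1 / 6, 1 / 2])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(f1=st.floats(-5, 5), f2=st.floats(-5, 5))
def test_zero_interaction_factorizes(f1, f2):
    s = state_probs(f1, f2, 0.0)
    assert s.psi11 * s.psi00 == pytest.approx(s.psi10 * s.psi01, rel=1e-9)


def test_state_probs_overflow_safe():
    s = state_probs(800.0, 800.0, 800.0)
    assert np.isfinite(s.as_array()).all()
    assert s.psi11 == pytest.approx(1.0)


def test_state_probs_shift_invariance():
    # adding a constant to all four log-weights is adding c to f1 and f2
    # and -c to their sum's correction; directly: scaling all weights
    a = state_probs(1.0, -0.5, 0.3).as_array()
    lw = np.array([0.0, 1.0, -0.5, 1.0 - 0.5 + 0.3]) + 7.0
    w = np.exp(lw)
    assert a == pytest.approx(w / w.sum(), rel=1e-12)


def test_multi_likelihood_spot_value():
    # one detection for species 1, none for species 2, uniform states, p=0.5:
    # 0.25*0.125*0.125 (both present) + 0.25*0.125 (only sp1 present)
    ll = multi_site_log_likelihood([1, 0, 0], [0, 0, 0], state_probs(0, 0, 0), 0.5, 0.5)
    assert np.exp(ll) == pytest.approx(0.03515625, abs=1e-12)


def test_both_detected_only_psi11_contributes():
    states = StateProbs(0.1, 0.2, 0.3, 0.4)
    ll = multi_site_log_likelihood([1, 0], [0, 1], states, 0.6, 0.7)
    expected = 0.4 * (0.6 * 0.4) * (0.7 * 0.3)
    assert np.exp(ll) == pytest.approx(expected, abs=1e-12)


def test_certain_joint_presence_reduces_to_product():
    states = StateProbs(0.0, 0.0, 0.0, 1.0)
    y1, y2 = [1, 0, 1], [0, 0, 1]
    ll = multi_site_log_likelihood(y1, y2, states, 0.55, 0.35)
    from occumeta.single import site_log_likelihood

    # psi=1 single-species likelihood is just the binomial detection part
    part1 = site_log_likelihood(y1, 1.0 - 1e-15, 0.55)
    part2 = site_log_likelihood(y2, 1.0 - 1e-15, 0.35)
    assert ll == pytest.approx(part1 + part2, abs=1e-9)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    f1=st.floats(-2, 2), f2=st.floats(-2, 2), f12=st.floats(-2, 2),
    p1=st.floats(0.05, 0.95), p2=st.floats(0.05, 0.95), k=st.integers(1, 3),
)
def test_paired_likelihood_normalizes(f1, f2, f12, p1, p2, k):
    states = state_probs(f1, f2, f12)
    total = sum(
        np.exp(multi_site_log_likelihood(y1, y2, states, p1, p2))
        for y1 in itertools.product((0, 1), repeat=k)
        for y2 in itertools.product((0, 1), repeat=k)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_conditional_occupancy_examples():
    assert conditional_occupancy(state_probs(0, 0, 0), 1, True) == pytest.approx(0.5)
    assert conditional_occupancy(state_probs(0, 0, 0), 1, False) == pytest.approx(0.5)
    s = state_probs(0, 0, np.log(3))
    assert conditional_occupancy(s, 1, True) == pytest.approx(0.75)
    with pytest.raises(ValueError, match="conditioning event"):
        conditional_occupancy(StateProbs(0.0, 0.0, 0.5, 0.5), 1, False)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(f1=st.floats(-2, 2), f2=st.floats(-2, 2), f12=st.floats(0.01, 3))
def test_positive_interaction_raises_conditional(f1, f2, f12):
    s = state_probs(f1, f2, f12)
    assert conditional_occupancy(s, 1, True) > conditional_occupancy(s, 1, False)
    assert conditional_occupancy(s, 2, True) > conditional_occupancy(s, 2, False)


def test_parse_multi_spec_headline():
    spec = parse_multi_spec(
        "psi[mcr] ~ ecosystem, psi[pmo] ~ ecosystem + sqrt(numeric.add.date), "
        "psi[mcr:pmo] ~ ecosystem"
    )
    assert spec.f1_terms == "ecosystem"
    assert "sqrt" in spec.f2_terms
    assert spec.f12_terms == "ecosystem"
    assert spec.species_names == ("mcr", "pmo")


def test_headline_model_has_twelve_parameters():
    # ecosystem (3) + ecosystem+sqrt(date) (4) + ecosystem (3) + 2 detection
    cfg = SimulationConfig.constant_multi(400, 0.2, 0.1, 0.5, 0.5, 0.5, seed=21)
    sim = simulate_multi(cfg)
    spec = parse_multi_spec(
        "psi[1] ~ ecosystem, psi[2] ~ ecosystem + sqrt(numeric.add.date), psi[12] ~ ecosystem"
    )
    f = fit_multi(sim.history1, sim.history2, sim.site_table, spec, n_starts=2)
    assert f.n_params == 12
    assert f.aic == pytest.approx(-2 * f.loglik + 24)


def test_independent_species_interval_covers_zero():
    cfg = SimulationConfig.constant_multi(3000, 0.3, -0.2, 0.0, 0.5, 0.45, seed=17)
    sim = simulate_multi(cfg)
    f = fit_multi(sim.history1, sim.history2, sim.site_table, n_starts=2)
    j = f.blocks["f12"].start
    assert abs(f.coefs[j]) < 1.96 * f.se()[j] + 0.05


def test_tiny_instance_dominates_coarse_grid():
    y1 = np.array([[1, 1, 0], [0, 0, 0], [1, 0, 0], [0, 0, 0],
                   [1, 1, 1], [0, 1, 0], [0, 0, 0], [1, 0, 1]])
    y2 = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0],
                   [1, 0, 1], [0, 0, 0], [0, 1, 0], [1, 1, 1]])
    from occumeta.history import DetectionHistory

    ids = [f"s{i}" for i in range(8)]
    h1 = DetectionHistory(ids, y1, ("a1", "a2", "a3"))
    h2 = DetectionHistory(ids, y2, ("b1", "b2", "b3"))
    f = fit_multi(h1, h2, None, n_starts=3)

    grid = np.linspace(-2.0, 2.0, 5)
    best_grid = -np.inf
    for f1 in grid:
        for f2 in grid:
            for f12 in grid:
                states = state_probs(f1, f2, f12)
                for a1 in grid:
                    for a2 in grid:
                        p1, p2 = 1 / (1 + np.exp(-a1)), 1 / (1 + np.exp(-a2))
                        ll = sum(
                            multi_site_log_likelihood(y1[i], y2[i], states, p1, p2)
                            for i in range(8)
                        )
                        best_grid = max(best_grid, ll)
    assert f.loglik >= best_grid - 1e-9


def test_f12_zero_factorizes_into_single_species_fits():
    cfg = SimulationConfig.constant_multi(600, 0.2, -0.1, 0.8, 0.5, 0.45, seed=23)
    sim = simulate_multi(cfg)
    f = fit_multi(sim.history1, sim.history2, sim.site_table, n_starts=2, fix_f12_zero=True)
    f1s = fit_single(sim.history1, sim.site_table, "p ~ 1, psi ~ 1")
    f2s = fit_single(sim.history2, sim.site_table, "p ~ 1, psi ~ 1")
    assert f.loglik == pytest.approx(f1s.loglik + f2s.loglik, abs=1e-4)


def _flat_fit(n=50, seed=31):
    cfg = SimulationConfig.constant_multi(n, 0.0, 0.0, 0.0, 0.5, 0.5, seed=seed)
    sim = simulate_multi(cfg)
    f = fit_multi(sim.history1, sim.history2, sim.site_table, n_starts=1)
    f.coefs = np.zeros_like(f.coefs)
    f.cov = np.zeros_like(f.cov)
    return f, sim.site_table


def test_zero_coefficient_curves_are_flat_at_half():
    f, site_table = _flat_fit()
    curves = predict_conditional_curves(f, site_table.iloc[:4], n_boot=10, seed=0)
    assert curves["estimate"].to_numpy() == pytest.approx(0.5)


def test_zero_bootstrap_draws_omit_intervals():
    f, site_table = _flat_fit()
    curves = predict_conditional_curves(f, site_table.iloc[:3], n_boot=0)
    assert "lower" not in curves.columns and "upper" not in curves.columns
    assert len(curves) == 6  # two conditioning states per grid row


def test_delta_and_bootstrap_intervals_agree():
    cfg = SimulationConfig.constant_multi(3000, 0.4, -0.3, 1.0, 0.5, 0.45, seed=29)
    sim = simulate_multi(cfg)
    f = fit_multi(sim.history1, sim.history2, sim.site_table, n_starts=2)
    grid = sim.site_table.iloc[:3]
    boot = predict_conditional_curves(f, grid, n_boot=2000, method="bootstrap", seed=1)
    delta = predict_conditional_curves(f, grid, method="delta")
    for col in ("lower", "upper"):
        assert boot[col].to_numpy() == pytest.approx(delta[col].to_numpy(), abs=0.05)
    assert ((boot["lower"] > 0) & (boot["upper"] < 1)).all()
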