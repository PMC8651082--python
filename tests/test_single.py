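"""Single-species occupancy likelihood, MLE, AIC ranking, and prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from occumeta.history import DetectionHistory
from occumeta.simulate import SimulationConfig, simulate_single
from occumeta.single import (
    OccuModelSpec,
    delta_aic,
    fit,
    naive_occupancy,
    parse_model_spec,
    predict_detection,
    predict_occupancy,
    site_log_likelihood,
)

FOUR_SITES = DetectionHistory(
    ["s1", "s2", "s3", "s4"],
    np.array([[1, 1, 0], [0, 0, 0], [1, 0, 0], [0, 0, 0]]),
    ("k1", "k2", "k3"),
)


@pytest.mark.parametrize(
    "y,psi,p,expected",
    [
        ((1, 0, 1), 0.5, 0.5, 0.0625),
        ((0, 0, 0), 0.5, 0.5, 0.5625),
        ((0, 0), 1.0, 0.3, 0.49),
    ],
)
def test_site_log_likelihood_spot_values(y, psi, p, expected):
    assert np.exp(site_log_likelihood(y, psi, p)) == pytest.approx(expected, abs=1e-12)


def test_site_log_likelihood_rejects_nonbinary():
    with pytest.raises(ValueError):
        site_log_likelihood((0, 2, 0), 0.5, 0.5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    psi=st.floats(0.01, 0.99),
    p=st.floats(0.01, 0.99),
    k=st.integers(1, 4),
)
def test_likelihood_normalizes_over_all_histories(psi, p, k):
    total = sum(
        np.exp(site_log_likelihood(y, psi, p)) for y in itertools.product((0, 1), repeat=k)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(p=st.floats(0.05, 0.95), lo=st.floats(0.05, 0.5), hi=st.floats(0.5, 0.95))
def test_detected_history_likelihood_increases_in_psi(p, lo, hi):
    if lo >= hi:
        lo, hi = hi, lo
    if hi - lo < 1e-6:
        return
    y = (1, 0, 1)
    assert site_log_likelihood(y, hi, p) > site_log_likelihood(y, lo, p)


def _grid_oracle(history, resolution=1e-3):
    """Brute-force maximizer of the joint likelihood over (psi, p)."""
    grid = np.arange(resolution, 1.0, resolution)
    best, arg = -np.inf, None
    d = history.y.sum(axis=1)
    k = history.n_surveys
    for psi in grid:
        # vectorized over p for speed
        for p in grid:
            ll = 0.0
            for di in d:
                if di > 0:
                    ll += np.log(psi) + di * np.log(p) + (k - di) * np.log1p(-p)
                else:
                    ll += np.log(psi * (1 - p) ** k + 1 - psi)
            if ll > best:
                best, arg = ll, (psi, p)
    return arg, best


def test_intercept_only_mle_matches_grid_oracle():
    f = fit(FOUR_SITES, None, "p ~ 1, psi ~ 1")
    (psi_g, p_g), _ = _grid_oracle(FOUR_SITES)
    psi_hat, p_hat = expit(f.coefs)
    assert psi_hat == pytest.approx(psi_g, abs=2e-3)
    assert p_hat == pytest.approx(p_g, abs=2e-3)
    assert f.converged


def test_perfect_detection_hits_boundary():
    hist = DetectionHistory(["a", "b"], np.ones((2, 3), dtype=int), ("k1", "k2", "k3"))
    f = fit(hist, None, "p ~ 1, psi ~ 1")
    assert f.boundary
    assert expit(f.coefs[0]) > 1 - 1e-4 and expit(f.coefs[1]) > 1 - 1e-4


def test_simulation_recovery_within_three_se():
    cfg = SimulationConfig.constant_single(2000, 0.6, 0.4, seed=7)
    sim = simulate_single(cfg)
    f = fit(sim.history, sim.site_table, "p ~ 1, psi ~ 1")
    se = f.se()
    assert abs(f.coefs[0] - logit(0.6)) < 3 * se[0]
    assert abs(f.coefs[1] - logit(0.4)) < 3 * se[1]


def test_naive_occupancy_examples():
    assert naive_occupancy(FOUR_SITES) == 0.5
    allzero = DetectionHistory(["a"], np.zeros((1, 3), dtype=int), ("k1", "k2", "k3"))
    assert naive_occupancy(allzero) == 0.0


def test_naive_underestimates_model_psi():
    cfg = SimulationConfig.constant_single(5000, 0.6, 0.4, seed=3)
    sim = simulate_single(cfg)
    f = fit(sim.history, sim.site_table, "p ~ 1, psi ~ 1")
    assert naive_occupancy(sim.history) < expit(f.coefs[0])


def test_aic_and_delta_aic():
    class Stub:
        def __init__(self, ll, k):
            self.loglik, self.n_params = ll, k
            self.spec = f"stub{k}"

        @property
        def aic(self):
            return -2 * self.loglik + 2 * self.n_params

    assert Stub(-5, 2).aic == 14
    table = delta_aic([Stub(-5, 2), Stub(-6, 2), Stub(-5, 2)], ["a", "b", "c"])
    assert list(table["dAIC"]) == [0.0, 0.0, 2.0]
    assert list(table["model"]) == ["a", "c", "b"]  # ties keep input order


def test_ecosystem_covariate_wins_on_structured_data():
    # distinct per-ecosystem occupancy: the ecosystem model must rank first
    cfg = SimulationConfig(
        n_sites=1500,
        seed=9,
        psi_terms="ecosystem",
        psi_coefs=(logit(0.2), 2.5, 1.2),  # engineered ref, environmental, host
        p_coefs=(logit(0.5),),
    )
    sim = simulate_single(cfg)
    f_null = fit(sim.history, sim.site_table, "p ~ 1, psi ~ 1")
    f_eco = fit(sim.history, sim.site_table, "p ~ 1, psi ~ ecosystem")
    assert f_eco.n_params == 4
    table = delta_aic([f_null, f_eco], ["null", "ecosystem"])
    assert table.loc[table["model"] == "ecosystem", "dAIC"].iloc[0] == 0.0


def test_aic_invariant_to_ecosystem_reference_level():
    cfg = SimulationConfig(
        n_sites=800, seed=13, psi_terms="ecosystem",
        psi_coefs=(0.0, 1.0, -0.5), p_coefs=(0.0,),
    )
    sim = simulate_single(cfg)
    f1 = fit(sim.history, sim.site_table, "p ~ 1, psi ~ ecosystem")
    # renaming categories permutes the lexicographic reference level
    relabel = {"engineered": "z-engineered", "environmental": "a-environmental",
               "host-associated": "m-host"}
    st2 = sim.site_table.copy()
    st2["ecosystem"] = st2["ecosystem"].map(relabel)
    f2 = fit(sim.history, st2, "p ~ 1, psi ~ ecosystem")
    assert f1.aic == pytest.approx(f2.aic, abs=1e-6)


def test_single_survey_flags_nonidentifiability():
    hist = DetectionHistory(["a", "b", "c", "d"], np.array([[1], [0], [1], [0]]), ("k1",))
    f = fit(hist, None, "p ~ 1, psi ~ 1")
    assert any("K=1" in w for w in f.warnings)
    # only the product psi*p is pinned down, at the detection frequency
    assert expit(f.coefs[0]) * expit(f.coefs[1]) == pytest.approx(0.5, abs=1e-3)


def test_never_detected_flags_warning():
    hist = DetectionHistory(["a", "b"], np.zeros((2, 3), dtype=int), ("k1", "k2", "k3"))
    f = fit(hist, None, "p ~ 1, psi ~ 1")
    assert any("never detected" in w for w in f.warnings)


def test_rank_deficient_design_is_an_error():
    st_const = pd.DataFrame({"latitude": [5.0, 5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="rank-deficient"):
        fit(FOUR_SITES, st_const, "p ~ 1, psi ~ latitude")


def test_parse_model_spec_roundtrip():
    spec = parse_model_spec("p ~ sqrt(numeric.add.date), psi ~ latitude")
    assert spec.psi_terms == "latitude"
    assert spec.p_terms == "sqrt(numeric.add.date)"
    assert parse_model_spec("Ψ ~ ecosystem, p ~ 1").psi_terms == "ecosystem"
    with pytest.raises(ValueError):
        parse_model_spec("psi ~ 1")


def test_predict_occupancy_interval_matches_closed_form():
    f = fit(FOUR_SITES, None, "p ~ 1, psi ~ 1")
    newdata = pd.DataFrame(index=[0])
    pred = predict_occupancy(f, newdata)
    v11 = f.cov[0, 0]
    lo = expit(f.coefs[0] - 1.959963984540054 * np.sqrt(v11))
    hi = expit(f.coefs[0] + 1.959963984540054 * np.sqrt(v11))
    assert pred["lower"].iloc[0] == pytest.approx(lo, abs=1e-10)
    assert pred["upper"].iloc[0] == pytest.approx(hi, abs=1e-10)
    assert 0 < pred["lower"].iloc[0] <= pred["estimate"].iloc[0] <= pred["upper"].iloc[0] < 1


def test_predict_with_zero_coefficients_gives_half():
    f = fit(FOUR_SITES, None, "p ~ 1, psi ~ 1")
    f.coefs = np.zeros_like(f.coefs)
    f.cov = np.zeros_like(f.cov)
    pred = predict_occupancy(f, pd.DataFrame(index=[0]))
    assert pred["estimate"].iloc[0] == 0.5
    # zero linear-predictor variance collapses the interval to the estimate
    assert pred["lower"].iloc[0] == pred["upper"].iloc[0] == 0.5
    assert predict_detection(f, pd.DataFrame(index=[0]))["estimate"].iloc[0] == 0.5


def test_predict_rejects_unseen_ecosystem_level():
    cfg = SimulationConfig(n_sites=300, seed=2, psi_terms="ecosystem",
                           psi_coefs=(0.0, 0.5, 0.5), p_coefs=(0.0,))
    sim = simulate_single(cfg)
    f = fit(sim.history, sim.site_table, "p ~ 1, psi ~ ecosystem")
    bad = pd.DataFrame({"ecosystem": ["lunar"]})
    with pytest.raises(ValueError, match="unseen"):
        predict_occupancy(f, bad)
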