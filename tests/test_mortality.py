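"""Cox hazard ratios, prevalence smoothing, and life-table anchoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import activelife as al
from activelife.mortality import (
    HazardRatioModel,
    anchor_death_probs,
    estimate_prevalence,
    fit_hazard_ratios,
)
from activelife.synthetic import _coeffs_from_rates_at_75


def _static_state_params(n, hr2=2.2):
    """Frozen disability states isolate the Cox estimator."""
    return al.default_params(
        al.BINARY, n=n,
        rate_coeffs=_coeffs_from_rates_at_75({(1, 2): 1e-6, (2, 1): 1e-6}),
        hazard_ratios=(1.0, hr2),
    )


def test_hazard_ratio_recovery_static_states():
    params = _static_state_params(50_000)
    staged = al.add_states(al.generate_cohort(params, seed=12), al.BINARY)
    hr = fit_hazard_ratios(staged, al.BINARY)
    assert hr.gamma[0] == 0.0 and hr.delta[0] == 0.0  # reference by construction
    assert abs(hr.gamma[1] - np.log(2.2)) < 3.0 * hr.se_gamma[1]
    assert abs(hr.delta[1]) < 3.0 * hr.se_delta[1]  # no true age interaction


def test_hazard_ratio_null_case():
    """Identical mortality in all states: fitted HRs within 3 SE of 1."""
    params = al.default_params(al.THREE_LEVEL, n=50_000, hazard_ratios=(1.0, 1.0, 1.0))
    staged = al.add_states(al.generate_cohort(params, seed=13), al.THREE_LEVEL)
    hr = fit_hazard_ratios(staged, al.THREE_LEVEL)
    for s in (2, 3):
        assert abs(hr.gamma[s - 1]) < 3.0 * hr.se_gamma[s - 1]


def test_age_interaction_default_depends_on_scheme(three_level_fit):
    assert three_level_fit.hazard_ratios.with_age_interaction  # k = 3
    params = al.default_params(al.FIVE_LEVEL, n=20_000)
    staged = al.add_states(al.generate_cohort(params, seed=2), al.FIVE_LEVEL)
    hr5 = fit_hazard_ratios(staged, al.FIVE_LEVEL)
    assert not hr5.with_age_interaction


def test_zero_death_state_is_flagged_and_blocks_anchoring():
    rows = []
    rng = np.random.default_rng(0)
    for i in range(300):
        # deaths happen only in state 1
        dead = i % 3 == 0
        rows.append({
            "age_base": 65.0 + rng.uniform(0, 20), "interval_years": 2.0,
            "state_b": 1.0 if i % 2 == 0 else 2.0, "state_f": np.nan,
            "dead": int(dead and i % 2 == 0), "responded_followup": 0,
            "time_to_death_years": 1.0 if (dead and i % 2 == 0) else np.nan,
        })
    panel = pd.DataFrame(rows)
    hr = fit_hazard_ratios(panel, al.BINARY, with_age_interaction=False)
    assert hr.flags.get("zero_death_states") == [2]
    assert np.isnan(hr.gamma[1])
    ages = np.array([65.0])
    lt = pd.DataFrame({"age": ages, "qx": [0.1]})
    with pytest.raises(ValueError):
        anchor_death_probs(lt, hr, np.array([[0.5, 0.5]]), ages)


def test_no_deaths_panel_falls_back_to_unit_hazard_ratios():
    params = al.default_params(al.BINARY, n=2_000, gompertz_level=0.0)
    staged = al.add_states(al.generate_cohort(params, seed=1), al.BINARY)
    hr = fit_hazard_ratios(staged, al.BINARY)
    assert hr.flags.get("no_deaths")
    assert np.allclose(hr.hr(np.array([70.0])), 1.0)


def test_cox_fit_matches_lifelines():
    """PHReg-based episode fit agrees with lifelines' time-varying Cox."""
    from lifelines import CoxTimeVaryingFitter

    from activelife.mortality import _episodes

    params = al.default_params(al.BINARY, n=4_000)
    staged = al.add_states(al.generate_cohort(params, seed=30), al.BINARY)
    hr = fit_hazard_ratios(staged, al.BINARY, with_age_interaction=False)
    ep = _episodes(staged)
    ep = ep.assign(id=np.arange(len(ep)), state_2=(ep["state"] == 2).astype(float))
    ctv = CoxTimeVaryingFitter()
    ctv.fit(ep[["id", "start", "stop", "event", "state_2"]], id_col="id",
            start_col="start", stop_col="stop", event_col="event",
            show_progress=False)
    assert hr.gamma[1] == pytest.approx(float(ctv.params_["state_2"]), abs=1e-6)


def test_prevalence_single_state_and_normalisation():
    panel = pd.DataFrame({
        "state_b": [2.0] * 500,
        "age_base": np.linspace(65, 90, 500),
    })
    ages = np.arange(65.0, 97.0, 2.0)
    pi = estimate_prevalence(panel, al.THREE_LEVEL, ages)
    assert np.allclose(pi[:, 1], 1.0)
    assert np.allclose(pi.sum(axis=1), 1.0)


def test_prevalence_recovery(three_level_panel):
    """Smoothed prevalence within 0.02 of the age-constant generating mix."""
    staged = al.add_states(three_level_panel, al.THREE_LEVEL)
    ages = np.arange(65.0, 97.0, 2.0)
    pi = estimate_prevalence(staged, al.THREE_LEVEL, ages)
    assert np.allclose(pi.sum(axis=1), 1.0, atol=1e-9)
    truth = np.array([0.624, 0.164, 0.212])
    assert np.abs(pi - truth).max() < 0.02


def test_anchoring_identity_and_trivial_case():
    ages = np.arange(65.0, 97.0, 2.0)
    lt = al.generate_reference_lifetable(0.02, 0.08, ages)
    k = 3
    hr = HazardRatioModel(k, np.log([1.0, 1.5, 3.0]), np.zeros(k),
                          np.zeros(k), np.zeros(k), False)
    pi = np.tile([0.6, 0.25, 0.15], (len(ages), 1))
    q = anchor_death_probs(lt, hr, pi, ages)
    # prevalence-weighted mean reproduces the life table at every age
    assert np.abs((q * pi).sum(axis=1) - lt["qx"].to_numpy()).max() < 1e-10
    # ordering follows the hazard ratios
    assert np.all(q[:, 0] < q[:, 1]) and np.all(q[:, 1] < q[:, 2])
    # all HR = 1: every state gets the life-table probability
    hr1 = HazardRatioModel(k, np.zeros(k), np.zeros(k), np.zeros(k), np.zeros(k), False)
    q1 = anchor_death_probs(lt, hr1, pi, ages)
    assert np.abs(q1 - lt["qx"].to_numpy()[:, None]).max() < 1e-10


def test_anchoring_two_state_bisection_oracle():
    """Hand bisection on a fine grid reproduces the solver's q_j."""
    ages = np.array([65.0])
    lt = pd.DataFrame({"age": ages, "qx": [0.1]})
    hr = HazardRatioModel(2, np.log([1.0, 3.0]), np.zeros(2),
                          np.zeros(2), np.zeros(2), False)
    pi = np.array([[0.5, 0.5]])
    q = anchor_death_probs(lt, hr, pi, ages)
    Hs = np.linspace(1e-9, 1.0, 2_000_001)
    f = 0.5 * (1 - np.exp(-Hs)) + 0.5 * (1 - np.exp(-3 * Hs)) - 0.1
    H = Hs[np.argmin(np.abs(f))]
    assert q[0, 0] == pytest.approx(1 - np.exp(-H), abs=1e-6)
    assert q[0, 1] == pytest.approx(1 - np.exp(-3 * H), abs=1e-6)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    w=st.floats(0.05, 0.95),
    loghr=st.floats(0.0, 2.5),
    qx=st.floats(0.005, 0.6),
)
def test_anchoring_identity_property(w, loghr, qx):
    """For any prevalence/HR/q the weighted mean equals q to 1e-10."""
    ages = np.array([71.0])
    lt = pd.DataFrame({"age": ages, "qx": [qx]})
    hr = HazardRatioModel(2, np.array([0.0, loghr]), np.zeros(2),
                          np.zeros(2), np.zeros(2), False)
    pi = np.array([[w, 1.0 - w]])
    q = anchor_death_probs(lt, hr, pi, ages)
    assert abs(float((q * pi).sum()) - qx) < 1e-10
    assert q[0, 1] >= q[0, 0]


def test_anchoring_no_root_error_names_age():
    ages = np.array([67.0])
    lt = pd.DataFrame({"age": ages, "qx": [0.5]})
    # tiny hazard ratios make q = 0.5 unreachable within H <= 20
    hr = HazardRatioModel(2, np.log([1.0, 1.0]) - 8.0, np.zeros(2),
                          np.zeros(2), np.zeros(2), False)
    hr.gamma = np.array([-8.0, -8.0])  # shrink even the reference state
    with pytest.raises(ValueError, match="67"):
        anchor_death_probs(lt, hr, np.array([[0.5, 0.5]]), ages)
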