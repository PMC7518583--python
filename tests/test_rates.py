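"""Transition-rate estimation: observation building, Poisson fits, conversion."""

import numpy as np
import pandas as pd
import pytest

import activelife as al
from activelife.rates import PairRate, build_transition_observations, fit_rates
from activelife.synthetic import _coeffs_from_rates_at_75


def _staged(rows):
    """Minimal staged panel from (state_b, state_f, dead, responded) tuples."""
    df = pd.DataFrame(rows, columns=["state_b", "state_f", "dead", "responded_followup"])
    df["age_base"] = 70.0
    df["interval_years"] = 2.0
    return df


def test_observation_expansion_and_exclusions():
    panel = _staged([
        (1, 1, 0, 1),          # stayer: 2 observations, both events 0
        (1, 3, 0, 1),          # mover: event on 1->3
        (2, np.nan, 0, 1),     # missing follow-up stage: excluded
        (1, np.nan, 1, 0),     # died: excluded
        (3, np.nan, 0, 0),     # non-response: excluded
    ])
    obs = build_transition_observations(panel, al.THREE_LEVEL)
    assert len(obs) == 4  # 2 usable respondents x (k-1)=2 destinations
    assert obs["event"].sum() == 1
    assert obs.loc[obs["event"] == 1, ["origin", "dest"]].values.tolist() == [[1, 3]]
    assert (obs["age"] == 71.0).all()  # mid-interval age


def test_observation_errors():
    with pytest.raises(ValueError):
        build_transition_observations(_staged([]), al.BINARY)
    dead_only = _staged([(1, np.nan, 1, 0)])
    with pytest.raises(ValueError):
        build_transition_observations(dead_only, al.BINARY)


def test_all_stayers_give_zero_events_and_degenerate_pairs():
    panel = _staged([(1, 1, 0, 1)] * 30 + [(2, 2, 0, 1)] * 30)
    obs = build_transition_observations(panel, al.BINARY)
    assert obs["event"].sum() == 0
    coef = fit_rates(obs, al.BINARY)
    for pr in coef.pairs.values():
        assert pr.degenerate
        assert pr.mu(np.array([70.0]))[0] == 0.0


def test_prob_from_rate_closed_forms():
    assert al.prob_from_rate(0.0) == 0.0
    assert abs(al.prob_from_rate(0.5) - (1.0 - np.exp(-1.0))) < 1e-12
    assert al.prob_from_rate(50.0) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(al.prob_from_rate(np.array([0.0, 0.5])),
                       [0.0, 1 - np.exp(-1.0)])
    with pytest.raises(ValueError):
        al.prob_from_rate(-0.1)


def _gentle_binary_params(n):
    """Low rates and mortality: the pairwise model is nearly exact."""
    return al.default_params(
        al.BINARY, n=n,
        rate_coeffs=_coeffs_from_rates_at_75({(1, 2): 0.03, (2, 1): 0.03}),
        hazard_ratios=(1.0, 1.0),
        gompertz_level=0.002, gompertz_slope=0.0,
        single_transition=True,
    )


def test_rate_recovery_on_synthetic_data():
    """Fitted mu(75) within 3 delta-method SEs of truth at n = 50k."""
    params = _gentle_binary_params(50_000)
    panel = al.generate_cohort(params, seed=21)
    staged = al.add_states(panel, al.BINARY)
    obs = build_transition_observations(staged, al.BINARY)
    coef = fit_rates(obs, al.BINARY)
    for pair, true75 in (((1, 2), 0.03), ((2, 1), 0.03)):
        pr = coef.pairs[pair]
        assert not pr.degenerate and pr.converged
        err = abs(np.log(pr.mu(np.array([75.0]))[0]) - np.log(true75))
        assert err < 3.0 * pr.se_log_mu(75.0), (pair, err, pr.se_log_mu(75.0))


def test_estimator_consistency_bias_shrinks_with_n():
    """Mean |bias| of the fitted rate falls as the panel grows."""
    truth = np.log(0.02)
    err = {}
    for n in (5_000, 50_000):
        params = al.default_params(
            al.BINARY, n=n,
            rate_coeffs=_coeffs_from_rates_at_75({(1, 2): 0.02, (2, 1): 0.02}),
            hazard_ratios=(1.0, 1.0), gompertz_level=0.0, gompertz_slope=0.0,
            single_transition=True,
        )
        errs = []
        for seed in (31, 32, 33):
            staged = al.add_states(al.generate_cohort(params, seed=seed), al.BINARY)
            coef = fit_rates(build_transition_observations(staged, al.BINARY),
                             al.BINARY)
            errs.append(abs(np.log(coef.pairs[(1, 2)].mu(np.array([75.0]))[0]) - truth))
        err[n] = np.mean(errs)
    assert err[50_000] < err[5_000]


def test_multi_jump_generation_attenuates_fitted_rates():
    """With several moves per interval, round trips hide transitions, so the
    fitted recovery rate falls below the generating one (sign regression)."""
    params = al.default_params(al.THREE_LEVEL, n=50_000)  # multi-jump default
    staged = al.add_states(al.generate_cohort(params, seed=17), al.THREE_LEVEL)
    coef = fit_rates(build_transition_observations(staged, al.THREE_LEVEL),
                     al.THREE_LEVEL)
    fitted = coef.pairs[(2, 1)].mu(np.array([75.0]))[0]
    assert fitted < 0.30  # generating value of the 2->1 intensity at 75


def test_doubling_exposure_halves_the_rate():
    params = _gentle_binary_params(20_000)
    staged = al.add_states(al.generate_cohort(params, seed=4), al.BINARY)
    obs = build_transition_observations(staged, al.BINARY)
    doubled = obs.assign(exposure=obs["exposure"] * 2.0)
    a = fit_rates(obs, al.BINARY).pairs[(1, 2)]
    b = fit_rates(doubled, al.BINARY).pairs[(1, 2)]
    assert a.alpha - b.alpha == pytest.approx(np.log(2.0), abs=1e-6)
    assert a.beta == pytest.approx(b.beta, abs=1e-8)


def _toy_coefficients(mu_const):
    coef = al.RateCoefficients("binary", 2)
    for (i, j) in ((1, 2), (2, 1)):
        coef.pairs[(i, j)] = PairRate(i, j, np.log(mu_const), 0.0, 0.1, 0.0,
                                      100, 10, True, False)
    return coef


def test_probabilities_on_grid_composition():
    ages = np.arange(65.0, 97.0, 2.0)
    tp = al.probabilities_on_grid(_toy_coefficients(0.2), ages)
    # age-constant rates: p constant and equal to the closed form
    assert np.allclose(tp.p[:, 0, 1], 1.0 - np.exp(-0.4))
    assert abs(tp.p[0, 0, 1] - 0.32968) < 1e-5
    assert np.all(tp.p[:, 0, 0] == 0.0)
    with pytest.raises(ValueError):
        al.probabilities_on_grid(_toy_coefficients(0.2), np.array([65.0, 68.0]))


def test_probabilities_hold_beyond_reporting_age():
    coef = al.RateCoefficients("binary", 2)
    coef.pairs[(1, 2)] = PairRate(1, 2, np.log(0.01) - 0.05 * 65, 0.05,
                                  0.1, 0.01, 100, 10, True, False)
    coef.pairs[(2, 1)] = PairRate(2, 1, np.log(0.01), 0.0, 0.1, 0.0, 100, 10, True, False)
    ages = np.arange(65.0, 115.0, 2.0)
    tp = al.probabilities_on_grid(coef, ages, hold_after=95.0)
    i95 = int(np.where(ages == 95.0)[0][0])
    assert np.all(tp.p[i95:, 0, 1] == tp.p[i95, 0, 1])
    assert tp.p[i95 - 1, 0, 1] < tp.p[i95, 0, 1]


def test_attach_death_probs_rescales_overflowing_rows():
    ages = np.array([65.0, 67.0])
    p = np.zeros((2, 2, 2))
    p[:, 0, 1] = 0.7
    p[:, 1, 0] = 0.1
    tp = al.TransitionProbabilities(ages, 2, p)
    q = np.array([[0.5, 0.1], [0.2, 0.1]])
    out = al.attach_death_probs(tp, q)
    # row (65, state 1): 0.7 + 0.5 > 1 -> p rescaled, q untouched
    assert out.q[0, 0] == 0.5
    assert out.p[0, 0, 1] == pytest.approx(0.5, abs=1e-9)
    # untouched row
    assert out.p[1, 0, 1] == 0.7
    assert np.all(out.stay() >= -1e-9)


def test_rate_coefficients_json_round_trip(tmp_path):
    coef = _toy_coefficients(0.15)
    path = tmp_path / "rates.json"
    coef.to_json(path)
    back = al.RateCoefficients.from_json(path)
    assert back.scheme_name == coef.scheme_name
    assert back.pairs.keys() == coef.pairs.keys()
    for key in coef.pairs:
        assert vars(back.pairs[key]) == vars(coef.pairs[key])
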