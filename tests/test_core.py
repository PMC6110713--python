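"""Utility model, softmax likelihood, and maximum-likelihood estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maximin_choice.core import (
    ChoicePair,
    ChoiceRecord,
    FitConfig,
    Lottery,
    SubjectParams,
    choice_probability,
    delta_u,
    fit_subject,
    grid_fit_oracle,
    negative_log_likelihood,
    utility,
)
from maximin_choice.synth import AgentSpec, DesignConfig, generate_lottery_set, simulate_choices


@pytest.mark.parametrize(
    "alpha, expected",
    [(0.0, 600.0), (1.0, 300.0), (0.5, 450.0)],
)
def test_utility_interpolates_min_and_ev(alpha, expected):
    assert utility(Lottery((300, 600, 900)), alpha) == pytest.approx(expected)


def test_utility_rejects_invalid_alpha():
    with pytest.raises(ValueError):
        utility(Lottery((300, 600, 900)), 1.5)


def test_lottery_validation():
    with pytest.raises(ValueError):
        Lottery((100.0, 200.0))
    with pytest.raises(ValueError):
        Lottery((-5.0, 0.0, 10.0))
    with pytest.raises(ValueError):
        Lottery((np.inf, 0.0, 10.0))


@given(
    outs=st.tuples(*[st.floats(0, 5000) for _ in range(3)]),
    alpha=st.floats(0, 1),
)
def test_utility_between_min_and_ev(outs, alpha):
    lot = Lottery(outs)
    u = utility(lot, alpha)
    assert min(lot.minimum, lot.ev) - 1e-9 <= u <= max(lot.minimum, lot.ev) + 1e-9


def test_choice_probability_symmetric_for_identical_options():
    lot = Lottery((100, 200, 300))
    pair = ChoicePair(lot, lot)
    assert choice_probability(pair, SubjectParams(0.3, 0.05)) == pytest.approx(0.5)


def test_choice_probability_hand_value():
    # U_a - U_b = 100 JPY at alpha=0, lam=0.01 -> logistic(1)
    pair = ChoicePair(Lottery((400, 500, 600)), Lottery((300, 400, 500)))
    p = choice_probability(pair, SubjectParams(0.0, 0.01))
    assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)


def test_choice_probability_deterministic_limit_and_no_overflow():
    pair = ChoicePair(Lottery((400, 500, 600)), Lottery((300, 400, 500)))
    p = choice_probability(pair, SubjectParams(0.0, 1e6))
    assert p == pytest.approx(1.0)
    # extreme products must not overflow
    assert np.isfinite(choice_probability(pair, SubjectParams(0.0, 1e300)))


@given(lam=st.floats(1e-4, 0.5), alpha=st.floats(0, 1))
def test_choice_probability_monotone_in_utility_gap(lam, alpha):
    gaps = [10.0, 50.0, 200.0]
    ps = []
    for g in gaps:
        pair = ChoicePair(Lottery((300 + g, 500 + g, 700 + g)), Lottery((300, 500, 700)))
        ps.append(choice_probability(pair, SubjectParams(alpha, lam)))
    assert ps[0] < ps[1] < ps[2]


def _records(pairs, choices, condition="Self"):
    return [
        ChoiceRecord(i, condition, p, c, rt=5.0) for i, (p, c) in enumerate(zip(pairs, choices))
    ]


def test_nll_uninformative_lam_gives_n_ln2(lottery_set):
    recs = _records(lottery_set, ["a"] * 36)
    nll = negative_log_likelihood(recs, SubjectParams(0.5, 1e-12))
    assert nll == pytest.approx(36 * np.log(2), abs=1e-6)


def test_nll_single_trial_and_additivity(lottery_set):
    params = SubjectParams(0.3, 0.02)
    recs = _records(lottery_set[:10], ["a", "b"] * 5)
    total = negative_log_likelihood(recs, params)
    parts = sum(negative_log_likelihood([r], params) for r in recs)
    assert total == pytest.approx(parts, rel=1e-12)
    assert total >= 0


def test_nll_matches_hand_softmax():
    pair = ChoicePair(Lottery((400, 500, 600)), Lottery((300, 400, 500)))
    rec = ChoiceRecord(0, "Self", pair, "a", 3.0)
    # P(a) = logistic(1) = 0.73106; -ln = 0.31326
    nll = negative_log_likelihood([rec], SubjectParams(0.0, 0.01))
    assert nll == pytest.approx(0.3132617, abs=1e-6)


def test_nll_empty_records_error():
    with pytest.raises(ValueError):
        negative_log_likelihood([], SubjectParams(0.5, 0.01))


def test_fit_recovers_simulated_alpha(lottery_set, rng):
    agent = AgentSpec(alpha_self=0.4, lam=0.02)
    recs = simulate_choices(lottery_set * 10, agent, "Self", rng)
    fit = fit_subject(recs)
    assert abs(fit.alpha_hat - 0.4) < 0.1
    assert fit.converged


def test_fit_beats_grid_oracle(lottery_set, rng):
    for alpha in (0.1, 0.5, 0.9):
        recs = simulate_choices(lottery_set, AgentSpec(alpha_self=alpha, lam=0.02), "Self", rng)
        fit = fit_subject(recs)
        oracle = grid_fit_oracle(
            recs, np.arange(0, 1.0001, 0.01), np.exp(np.linspace(np.log(1e-6), 0.0, 40))
        )
        assert fit.neg_log_lik <= oracle.neg_log_lik + 1e-6
        assert abs(fit.alpha_hat - oracle.alpha_hat) <= 0.02


def test_fit_random_choices_pushes_lam_to_lower_bound(lottery_set, rng):
    recs = [
        ChoiceRecord(i, "Self", p, "a" if rng.random() < 0.5 else "b", 5.0)
        for i, p in enumerate(lottery_set * 3)
    ]
    fit = fit_subject(recs)
    n = len(recs)
    assert fit.neg_log_lik <= n * np.log(2) + 1e-6
    assert fit.neg_log_lik >= n * np.log(2) - 2.0  # close to the chance bound
    assert fit.lam_hat < 0.005


def test_fit_deterministic_maximin_agent_hits_alpha_one(lottery_set):
    # always pick the larger-minimum option -> alpha at/near 1, lam capped
    recs = []
    for i, p in enumerate(lottery_set):
        choice = "a" if p.signed_min_advantage == "a" else "b"
        recs.append(ChoiceRecord(i, "Self", p, choice, 5.0))
    fit = fit_subject(recs)
    oracle = grid_fit_oracle(recs, np.arange(0, 1.0001, 0.01), [1e-4, 1e-3, 1e-2, 1e-1, 1.0])
    assert fit.alpha_hat > 0.85
    assert oracle.alpha_hat > 0.85
    assert fit.lam_capped


def test_grid_oracle_single_point(lottery_set):
    recs = _records(lottery_set[:5], ["a"] * 5)
    res = grid_fit_oracle(recs, [0.4], [0.02])
    assert res.alpha_hat == 0.4
    assert res.neg_log_lik == pytest.approx(
        negative_log_likelihood(recs, SubjectParams(0.4, 0.02))
    )


def test_grid_oracle_finds_true_params_on_noiseless_data(lottery_set):
    # near-deterministic agent whose generating point is on the grid
    params = SubjectParams(0.6, 1.0)
    recs = []
    for i, p in enumerate(lottery_set):
        ua = utility(p.option_a, 0.6)
        ub = utility(p.option_b, 0.6)
        recs.append(ChoiceRecord(i, "Self", p, "a" if ua > ub else "b", 5.0))
    res = grid_fit_oracle(recs, [0.2, 0.4, 0.6, 0.8], [0.01, 1.0])
    assert res.alpha_hat == 0.6


def test_fit_requires_two_trials(lottery_set):
    with pytest.raises(ValueError):
        fit_subject(_records(lottery_set[:1], ["a"]))


def test_tie_trials_contribute_ln2():
    lot = Lottery((100, 200, 300))
    rec = ChoiceRecord(0, "Self", ChoicePair(lot, lot), "b", 1.0)
    assert negative_log_likelihood([rec], SubjectParams(0.7, 0.5)) == pytest.approx(np.log(2))


@pytest.mark.parametrize("alpha, attr", [(0.0, "delta_ev"), (1.0, "delta_min")])
def test_delta_u_limits(simple_pair, alpha, attr):
    assert delta_u(simple_pair, alpha) == pytest.approx(getattr(simple_pair, attr))


def test_delta_u_hand_value_and_symmetry(simple_pair):
    assert delta_u(simple_pair, 0.5) == pytest.approx(25.0)
    flipped = ChoicePair(simple_pair.option_b, simple_pair.option_a)
    assert delta_u(flipped, 0.5) == pytest.approx(delta_u(simple_pair, 0.5))


@settings(max_examples=25, deadline=None)
@given(alpha=st.floats(0.05, 0.95))
def test_likelihood_prefers_generating_alpha_over_flip(alpha):
    rng = np.random.default_rng(int(alpha * 1e6))
    pairs = generate_lottery_set(DesignConfig(conflict_fraction=1.0), rng)
    recs = simulate_choices(pairs * 3, AgentSpec(alpha_self=alpha, lam=0.05), "Self", rng)
    lam = 0.05
    nll_true = negative_log_likelihood(recs, SubjectParams(alpha, lam))
    nll_flip = negative_log_likelihood(recs, SubjectParams(1 - alpha, lam))
    if abs(alpha - 0.5) > 0.1:
        assert nll_true < nll_flip + 5.0  # generous slack for sampling noise


def test_fit_config_start_grid_shape():
    cfg = FitConfig(n_alpha_starts=3, n_lam_starts=4)
    grid = cfg.start_grid()
    assert grid.shape == (12, 2)
    assert grid[:, 0].min() == 0.0 and grid[:, 0].max() == 1.0
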