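"""Synthetic generators: determinism, structural constraints, calibration."""

import numpy as np
import pandas as pd
import pytest

from maximin_choice.core import choice_probability
from maximin_choice.gaze import Layout
from maximin_choice.neuro import build_design, fit_glm
from maximin_choice.synth import (
    AgentSpec,
    DesignConfig,
    PopulationConfig,
    draw_agents,
    fmri_agent,
    frame_to_records,
    generate_lottery_set,
    is_dominated,
    make_event_schedule,
    records_to_frame,
    simulate_bold,
    simulate_choices,
    simulate_cohort,
    simulate_gaze,
    simulate_mouselab,
)


def test_lottery_set_deterministic_under_seed():
    a = generate_lottery_set(DesignConfig(), np.random.default_rng(3))
    b = generate_lottery_set(DesignConfig(), np.random.default_rng(3))
    assert a == b


def test_lottery_set_no_dominated_pairs(lottery_set):
    assert not any(is_dominated(p) for p in lottery_set)


def test_lottery_set_full_conflict():
    pairs = generate_lottery_set(DesignConfig(conflict_fraction=1.0), np.random.default_rng(4))
    for p in pairs:
        md = p.option_a.minimum - p.option_b.minimum
        ed = p.option_a.ev - p.option_b.ev
        assert np.sign(md) != np.sign(ed) and md != 0 and ed != 0


def test_lottery_set_conflict_fraction_and_decorrelation(lottery_set):
    n_conflict = sum(
        np.sign(p.option_a.minimum - p.option_b.minimum)
        != np.sign(p.option_a.ev - p.option_b.ev)
        for p in lottery_set
    )
    assert n_conflict >= int(0.75 * 36)
    dmin = np.array([p.delta_min for p in lottery_set])
    dev = np.array([p.delta_ev for p in lottery_set])
    assert abs(np.corrcoef(dmin, dev)[0, 1]) < 0.5
    assert dmin.std() > 0 and dev.std() > 0


def test_choice_frequency_matches_closed_form(lottery_set, agent):
    rng = np.random.default_rng(11)
    pair = lottery_set[0]
    p_true = choice_probability(pair, agent.params("Self"))
    recs = simulate_choices([pair] * 10_000, agent, "Self", rng)
    freq = np.mean([r.choice == "a" for r in recs])
    assert abs(freq - p_true) < 0.013


def test_simulate_choices_deterministic(lottery_set, agent):
    a = simulate_choices(lottery_set, agent, "Self", np.random.default_rng(5))
    b = simulate_choices(lottery_set, agent, "Self", np.random.default_rng(5))
    assert a == b


def test_rt_respects_deadline_and_condition_order(lottery_set):
    rng = np.random.default_rng(6)
    agent = AgentSpec()
    rs = simulate_choices(lottery_set * 30, agent, "Self", rng)
    ro = simulate_choices(lottery_set * 30, agent, "Other", rng)
    assert all(0 < r.rt < 30.0 for r in rs + ro)
    assert np.mean([r.rt for r in rs]) > np.mean([r.rt for r in ro])


def test_deterministic_maximin_agent_always_takes_larger_min(lottery_set):
    agent = AgentSpec(alpha_self=1.0, lam=1.0)
    recs = simulate_choices(lottery_set, agent, "Self", np.random.default_rng(8))
    for r in recs:
        assert r.choice == r.pair.signed_min_advantage


def test_mouselab_views_ordered_nonoverlapping_within_rt(lottery_set, agent, rng):
    recs = simulate_choices(lottery_set, agent, "Self", rng)
    views = simulate_mouselab(recs, agent, "Self", rng)
    assert (views.offset_s > views.onset_s).all()
    for tid, grp in views.groupby("trial_id"):
        s = grp.sort_values("onset_s")
        assert s.onset_s.iloc[0] >= 0
        assert (s.onset_s.values[1:] >= s.offset_s.values[:-1] - 1e-9).all()
        rt = next(r.rt for r in recs if r.trial_id == tid)
        assert s.offset_s.max() <= rt + 1e-9


def test_mouselab_first_view_bias_one_means_all_L(lottery_set, rng):
    agent = AgentSpec(first_view_low_bias_self=1.0)
    recs = simulate_choices(lottery_set, agent, "Self", rng)
    views = simulate_mouselab(recs, agent, "Self", rng)
    firsts = views.sort_values("onset_s").groupby("trial_id").first()
    assert (firsts["cell"] == "L").all()


def test_mouselab_null_dwell_gain_centers_at_zero(lottery_set, rng):
    agent = AgentSpec(dwell_min_gain_self=0.0)
    diffs = []
    for _ in range(30):
        recs = simulate_choices(lottery_set, agent, "Self", rng)
        views = simulate_mouselab(recs, agent, "Self", rng)
        views = views.assign(dur=views.offset_s - views.onset_s)
        for (tid,), grp in views.groupby(["trial_id"]):
            rec = next(r for r in recs if r.trial_id == tid)
            by_opt = grp.groupby("option")["dur"].sum()
            larger = rec.pair.signed_min_advantage
            smaller = "b" if larger == "a" else "a"
            diffs.append(by_opt.get(larger, 0.0) - by_opt.get(smaller, 0.0))
    assert abs(np.mean(diffs)) < 0.05


def test_gaze_samples_uniformly_spaced_and_deterministic(lottery_set, layout):
    agent = fmri_agent()
    recs = simulate_choices(lottery_set[:5], agent, "Self", np.random.default_rng(9))
    s1, t1 = simulate_gaze(recs, agent, "Self", layout, np.random.default_rng(10))
    s2, t2 = simulate_gaze(recs, agent, "Self", layout, np.random.default_rng(10))
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(t1, t2)
    for _, grp in s1.groupby("trial_id"):
        dts = np.diff(grp.t_s.values)
        assert np.allclose(dts, 1 / 500.0)


def test_gaze_truth_events_partition_trial(lottery_set, layout):
    agent = fmri_agent()
    recs = simulate_choices(lottery_set[:5], agent, "Self", np.random.default_rng(9))
    samples, truth = simulate_gaze(recs, agent, "Self", layout, np.random.default_rng(10))
    for tid, grp in truth.groupby("trial_id"):
        s = grp.sort_values("onset_idx")
        assert s.onset_idx.iloc[0] == 0
        assert (s.onset_idx.values[1:] == s.offset_idx.values[:-1]).all()
        n = (samples.trial_id == tid).sum()
        assert s.offset_idx.iloc[-1] == n


def test_bold_noiseless_recovery_and_shape_check(rng):
    ev = pd.DataFrame(
        [
            {"onset": 10.0, "duration": 3.0, "trial_type": "Self"},
            {"onset": 40.0, "duration": 2.5, "trial_type": "Other"},
        ]
    )
    X = build_design(ev, 2.0, 60, hpf_cutoff=None)
    betas = np.array([1.5, -0.7, 0.2])
    y = simulate_bold(X, betas, 0.0, rng)
    res = fit_glm(y, X)
    assert np.abs(res.params.values - betas).max() < 1e-10
    with pytest.raises(ValueError):
        simulate_bold(X, betas[:2], 0.0, rng)


def test_cohort_truth_structure_and_determinism():
    pop = PopulationConfig(n_subjects=8)
    c1 = simulate_cohort(pop, np.random.default_rng(20))
    c2 = simulate_cohort(pop, np.random.default_rng(20))
    pd.testing.assert_frame_equal(c1["truth"], c2["truth"])
    pd.testing.assert_frame_equal(c1["choices"], c2["choices"])
    assert len(c1["truth"]) == 8
    assert set(c1["choices"]["condition"]) == {"Self", "Other"}
    assert len(c1["choices"]) == 8 * 2 * 36
    assert ((c1["truth"]["alpha_self"] >= 0) & (c1["truth"]["alpha_self"] <= 1)).all()


def test_cohort_copula_induces_target_correlation():
    # generating-model correlation between empathy and the alpha contrast
    pop = PopulationConfig(n_subjects=4000, rho=0.4)
    agents = draw_agents(pop, np.random.default_rng(21))
    ec = np.array([a.empathic_concern for a in agents])
    contrast = np.array([a.alpha_other - a.alpha_self for a in agents])
    r = np.corrcoef(ec, contrast)[0, 1]
    assert abs(r - 0.4) < 0.06  # clipping of alpha/empathy mildly attenuates


def test_records_frame_roundtrip(lottery_set, agent, rng):
    recs = simulate_choices(lottery_set, agent, "Self", rng)
    back = frame_to_records(records_to_frame(recs))
    assert back == recs


def test_event_schedule_layout(lottery_set, rng):
    agent = fmri_agent()
    recs = {c: simulate_choices(lottery_set[:12], agent, c, rng) for c in ("Self", "Other", "Comp")}
    ev = make_event_schedule(recs, rng, alpha_by_condition={"Self": 0.4, "Other": 0.4, "Comp": 0.0})
    choice_ev = ev[ev.trial_type.isin(["Self", "Other", "Comp"])]
    assert len(choice_ev) == 36
    assert (ev[ev.trial_type == "cue"]["duration"] == 1.0).all()
    assert (ev[ev.trial_type == "response"]["duration"] == 0.0).all()
    assert choice_ev["du"].notna().all()
    assert ev.onset.is_monotonic_increasing
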