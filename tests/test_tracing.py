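"""Mouselab information-search analyses: quartile shares, first views,
dwell-difference mixed model."""

import numpy as np
import pandas as pd
import pytest

from maximin_choice.mixed import fit_logit_mixed
from maximin_choice.synth import (
    AgentSpec,
    DesignConfig,
    PopulationConfig,
    draw_agents,
    generate_lottery_set,
    simulate_choices,
    simulate_mouselab,
)
from maximin_choice.tracing import (
    dwell_difference_model,
    dwell_difference_table,
    first_view_counts,
    first_view_trials,
    fit_first_view_model,
    quartile_view_shares,
    trial_quartile_shares,
)


def _views(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "trial_id", "option", "cell",
                       "onset_s", "offset_s", "layout"]
    )


def test_single_full_trial_view_is_100pct_everywhere():
    v = _views([[0, "Self", 0, "a", "L", 0.0, 8.0, "LMH"]])
    shares = trial_quartile_shares(v, 8.0)
    assert np.allclose(shares[:, 0], 100.0)
    assert np.allclose(shares[:, 1:], 0.0)


def test_constructed_partition_q1_L_q4_H():
    v = _views(
        [
            [0, "Self", 0, "a", "L", 0.0, 2.0, "LMH"],
            [0, "Self", 0, "b", "H", 6.0, 8.0, "LMH"],
        ]
    )
    s = trial_quartile_shares(v, 8.0)
    assert s[0, 0] == pytest.approx(100.0)
    assert s[3, 2] == pytest.approx(100.0)
    assert np.isnan(s[1]).all() and np.isnan(s[2]).all()


def test_quartile_shares_match_millisecond_discretization(lottery_set, agent, rng):
    recs = simulate_choices(lottery_set[:8], agent, "Self", rng)
    views = simulate_mouselab(recs, agent, "Self", rng)
    for tid, tv in views.groupby("trial_id"):
        T = float(tv.offset_s.max())
        analytic = trial_quartile_shares(tv, T)
        # brute force: per-0.1ms time grid
        grid = np.linspace(0, T, 40001)[:-1] + T / 80002
        occupancy = np.zeros((4, 3))
        cell_idx = {"L": 0, "M": 1, "H": 2}
        q = np.minimum((grid / (T / 4)).astype(int), 3)
        for _, row in tv.iterrows():
            inside = (grid >= row.onset_s) & (grid < row.offset_s)
            np.add.at(occupancy, (q[inside], cell_idx[row.cell]), 1)
        tot = occupancy.sum(axis=1, keepdims=True)
        brute = np.where(tot > 0, occupancy / tot * 100, np.nan)
        assert np.nanmax(np.abs(analytic - brute)) < 0.1


def test_quartile_shares_invariant_to_time_rescaling():
    v = _views(
        [
            [0, "Self", 0, "a", "L", 0.2, 1.3, "LMH"],
            [0, "Self", 0, "b", "M", 1.5, 3.1, "LMH"],
            [0, "Self", 0, "a", "H", 3.3, 5.9, "LMH"],
        ]
    )
    s1 = trial_quartile_shares(v, 6.0)
    v2 = v.assign(onset_s=v.onset_s * 7.0, offset_s=v.offset_s * 7.0)
    s2 = trial_quartile_shares(v2, 42.0)
    assert np.allclose(s1, s2, equal_nan=True)


def test_quartile_shares_zero_decision_time_errors():
    v = _views([[0, "Self", 0, "a", "L", 0.0, 1.0, "LMH"]])
    with pytest.raises(ValueError):
        trial_quartile_shares(v, 0.0)


def test_quartile_view_shares_long_format(lottery_set, agent, rng):
    recs = simulate_choices(lottery_set[:6], agent, "Self", rng)
    views = simulate_mouselab(recs, agent, "Self", rng)
    views.insert(0, "subject_id", 0)
    out = quartile_view_shares(views)
    assert set(out.quartile) == {1, 2, 3, 4}
    # L+M+H sums to 100 within quartiles that have viewing
    sums = out.groupby(["subject_id", "condition", "quartile"])["share_pct"].sum()
    assert np.allclose(sums.dropna(), 100.0)


def test_first_view_counts_and_exclusion_invariants(lottery_set, rng):
    agent = AgentSpec()
    frames = []
    for sid in range(3):
        recs = simulate_choices(lottery_set, agent, "Self", rng)
        v = simulate_mouselab(recs, agent, "Self", rng)
        v.insert(0, "subject_id", sid)
        frames.append(v)
    views = pd.concat(frames, ignore_index=True)
    counts = first_view_counts(views)
    assert ((counts.n_first_L + counts.n_first_H + counts.n_excluded_M) == 36).all()
    # durations do not matter: squash all views to 1 ms
    squashed = views.assign(offset_s=views.onset_s + 0.001)
    pd.testing.assert_frame_equal(counts, first_view_counts(squashed))


def test_first_view_all_L_gives_zero_H(lottery_set, rng):
    agent = AgentSpec(first_view_low_bias_self=1.0)
    recs = simulate_choices(lottery_set, agent, "Self", rng)
    v = simulate_mouselab(recs, agent, "Self", rng)
    v.insert(0, "subject_id", 0)
    counts = first_view_counts(v)
    assert (counts.n_first_H == 0).all()
    assert (counts.n_first_L == 36).all()


def test_first_view_share_matches_binomial_rate(lottery_set):
    rng = np.random.default_rng(33)
    agent = AgentSpec(first_view_low_bias_self=0.7, first_view_low_bias_other=0.7)
    frames = []
    for rep in range(84):  # ~3000 trials; 0.03 tolerance is then ~3.6 SE
        recs = simulate_choices(lottery_set, agent, "Self", rng)
        v = simulate_mouselab(recs, agent, "Self", rng)
        v.insert(0, "subject_id", rep)
        frames.append(v)
    first = first_view_trials(pd.concat(frames, ignore_index=True))
    assert abs((first.first_cell == "L").mean() - 0.7) < 0.03


def _glmm_fixture():
    """Deterministic 12-subject Mouselab dataset (for the external oracle)."""
    rng = np.random.default_rng(42)
    pairs = generate_lottery_set(DesignConfig(), rng)
    agents = draw_agents(PopulationConfig(n_subjects=12), np.random.default_rng(100))
    frames = []
    for sid in range(12):
        for cond in ("Self", "Other"):
            recs = simulate_choices(pairs, agents[sid], cond, rng)
            v = simulate_mouselab(recs, agents[sid], cond, rng)
            v.insert(0, "subject_id", sid)
            frames.append(v)
    return pd.concat(frames, ignore_index=True)


def test_glmm_matches_lme4_reference():
    """Gauss-Hermite mixed logit reproduces lme4::glmer (nAGQ=25) estimates.

    Reference values were computed once with R lme4 on this exact
    deterministic dataset.
    """
    views = _glmm_fixture()
    res = fit_first_view_model(views)
    expected_coef = {"intercept": 0.4581457, "cond_self": 0.7868097, "layout_hml": -0.0644332}
    expected_se = {"intercept": 0.1812033, "cond_self": 0.1568851, "layout_hml": 0.1552163}
    table = res.table()
    for term, val in expected_coef.items():
        assert table.loc[term, "coef"] == pytest.approx(val, abs=2e-3)
        assert table.loc[term, "se"] == pytest.approx(expected_se[term], abs=2e-3)
    assert res.sigma_u == pytest.approx(0.4374274, abs=2e-3)
    assert res.loglik == pytest.approx(-493.34946, abs=5e-3)
    assert res.method == "glmm-gh"


def test_glmm_layout_null_effect_is_small():
    views = _glmm_fixture()
    res = fit_first_view_model(views).table()
    assert abs(res.loc["layout_hml", "z"]) < 2.5


def test_mixed_logit_handles_separation_with_penalty():
    rng = np.random.default_rng(2)
    n = 200
    g = np.repeat(np.arange(10), 20)
    x = rng.integers(0, 2, n).astype(float)
    y = x.copy()  # perfectly separated on x
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    with pytest.warns(UserWarning):
        res = fit_logit_mixed(y, X, g)
    assert res.penalized
    assert np.isfinite(res.coef).all()


def _dwell_dataset(gain_self, n_subjects=12, seed=50, dwell_bias_sd=0.0):
    rng = np.random.default_rng(seed)
    pairs = generate_lottery_set(DesignConfig(), rng)
    vf, cf = [], []
    from maximin_choice.synth import records_to_frame

    for sid in range(n_subjects):
        agent = AgentSpec(
            dwell_min_gain_self=gain_self,
            dwell_base_bias=float(rng.normal(0, dwell_bias_sd)),
        )
        for cond in ("Self", "Other"):
            recs = simulate_choices(pairs, agent, cond, rng)
            v = simulate_mouselab(recs, agent, cond, rng)
            v.insert(0, "subject_id", sid)
            vf.append(v)
            c = records_to_frame(recs)
            c.insert(0, "subject_id", sid)
            cf.append(c)
    return pd.concat(vf, ignore_index=True), pd.concat(cf, ignore_index=True)


def test_dwell_model_recovers_self_only_slope():
    views, choices = _dwell_dataset(gain_self=0.002, dwell_bias_sd=0.1)
    table = dwell_difference_table(views, choices)
    fit = dwell_difference_model(table).set_index(["condition", "term"])
    self_slope = fit.loc[("Self", "dmin")]
    other_slope = fit.loc[("Other", "dmin")]
    assert self_slope.coef == pytest.approx(0.002, abs=0.0005)
    assert self_slope.p < 0.01
    assert abs(other_slope.coef) < 0.0005


def test_dwell_lmm_matches_ols_when_no_subject_variance():
    import statsmodels.formula.api as smf

    views, choices = _dwell_dataset(gain_self=0.002, dwell_bias_sd=0.0)
    table = dwell_difference_table(views, choices)
    fit = dwell_difference_model(table).set_index(["condition", "term"])
    grp = table[table.condition == "Self"].assign(
        layout_hml=lambda d: (d.layout == "HML").astype(float)
    )
    ols = smf.ols("dwell_diff ~ dmin + dev + layout_hml", grp).fit()
    for term in ("dmin", "dev"):
        assert fit.loc[("Self", term), "coef"] == pytest.approx(ols.params[term], abs=1e-4)


def test_dwell_sign_convention_flips_with_option_labels():
    views, choices = _dwell_dataset(gain_self=0.002, n_subjects=3)
    t1 = dwell_difference_table(views, choices)
    flipped_views = views.assign(option=views.option.map({"a": "b", "b": "a"}))
    ren = {f"a_{s}": f"b_{s}" for s in ("low", "mid", "high")}
    ren.update({f"b_{s}": f"a_{s}" for s in ("low", "mid", "high")})
    flipped_choices = choices.rename(columns=ren)
    t2 = dwell_difference_table(flipped_views, flipped_choices)
    merged = t1.merge(t2, on=["subject_id", "condition", "trial_id"], suffixes=("_1", "_2"))
    # consistent relabeling leaves the physical quantity unchanged ...
    assert np.allclose(merged.dwell_diff_1, merged.dwell_diff_2)
    # ... while swapping which lottery the views refer to flips the sign
    t3 = dwell_difference_table(flipped_views, choices)
    merged3 = t1.merge(t3, on=["subject_id", "condition", "trial_id"], suffixes=("_1", "_3"))
    assert np.allclose(merged3.dwell_diff_1, -merged3.dwell_diff_3)


def test_dwell_model_constant_dmin_errors():
    views, choices = _dwell_dataset(gain_self=0.0, n_subjects=3)
    table = dwell_difference_table(views, choices)
    table["dmin"] = 100.0
    with pytest.raises(ValueError):
        dwell_difference_model(table)
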