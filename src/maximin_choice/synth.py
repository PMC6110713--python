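"""Synthetic study generator: choice sets, agents, process-tracing logs,
gaze streams, and BOLD series with known ground truth.

The generator emulates the structure of a two-condition (Self / Other) risky
choice study: 36 pairs of three-outcome lotteries per condition, agents who
choose by quasi-maximin utility + softmax, information search biased toward
minimum outcomes (more strongly when deciding for oneself), a trait
"empathic concern" score correlated with the Other-minus-Self difference in
maximin weights, and linear-model BOLD signal. Every simulator takes an
explicit ``numpy.random.Generator`` and emits ground truth alongside data so
each downstream analysis stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ChoicePair, ChoiceRecord, Lottery, choice_probability, SubjectParams

CELLS = ("L", "M", "H")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# choice-set design
# ---------------------------------------------------------------------------

@dataclass
class DesignConfig:
    """Lottery-pair designer settings.

    ``conflict_fraction`` is the share of pairs in which the larger-minimum
    option has the *smaller* expected value; without such min-vs-EV conflicts
    the maximin weight is unidentifiable from choices.
    """

    n_pairs: int = 36
    outcome_range: tuple[int, int] = (0, 2000)
    rounding: int = 10
    conflict_fraction: float = 0.75
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.conflict_fraction <= 1.0:
            raise ValueError("conflict_fraction must lie in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if self.outcome_range[1] <= self.outcome_range[0]:
            raise ValueError("outcome_range must be a positive interval")


def _draw_triple(cfg: DesignConfig, rng: np.random.Generator) -> np.ndarray:
    lo = cfg.outcome_range[0] // cfg.rounding
    hi = cfg.outcome_range[1] // cfg.rounding
    while True:
        vals = np.sort(rng.integers(lo, hi + 1, size=3)) * cfg.rounding
        if vals[0] < vals[1] < vals[2]:
            return vals.astype(float)


def is_dominated(pair: ChoicePair) -> bool:
    """True if one option is at least as good on every rank-ordered outcome
    (and strictly better on at least one)."""
    sa = np.sort(pair.option_a.outcomes)
    sb = np.sort(pair.option_b.outcomes)
    return bool(np.all(sa >= sb) or np.all(sb >= sa))


def generate_lottery_set(config: DesignConfig | None = None, rng=None) -> list[ChoicePair]:
    """Rejection-sample a set of non-dominated lottery pairs.

    Every pair has distinct minima and distinct expected values; a
    ``conflict_fraction`` share puts the larger minimum and the larger EV on
    opposite options. The finished set is checked for a usable spread of
    the trial-level parameters (|corr(dMin, dEV)| < 0.5, non-zero variance)
    and regenerated if the check fails.
    """
    config = config or DesignConfig()
    rng = _rng(rng)
    n_conflict = int(round(config.conflict_fraction * config.n_pairs))
    for _set_attempt in range(20):
        pairs: list[ChoicePair] = []
        ok = True
        for k in range(config.n_pairs):
            want_conflict = k < n_conflict
            for attempt in range(config.max_attempts):
                a = _draw_triple(config, rng)
                b = _draw_triple(config, rng)
                pair = ChoicePair(Lottery(tuple(a)), Lottery(tuple(b)))
                if is_dominated(pair):
                    continue
                md = pair.option_a.minimum - pair.option_b.minimum
                ed = pair.option_a.ev - pair.option_b.ev
                if md == 0 or ed == 0:
                    continue
                if want_conflict != (np.sign(md) != np.sign(ed)):
                    continue
                pairs.append(pair)
                break
            else:
                raise RuntimeError(
                    "could not satisfy the "
                    + ("min-vs-EV conflict" if want_conflict else "non-conflict")
                    + f" constraint in {config.max_attempts} attempts"
                )
        dmin = np.array([p.delta_min for p in pairs])
        dev = np.array([p.delta_ev for p in pairs])
        if dmin.std() == 0 or dev.std() == 0:
            ok = False
        elif config.n_pairs >= 4 and abs(np.corrcoef(dmin, dev)[0, 1]) >= 0.5:
            ok = False
        if ok:
            perm = rng.permutation(config.n_pairs)
            return [pairs[i] for i in perm]
    raise RuntimeError("could not generate a lottery set with decorrelated dMin/dEV")


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

@dataclass
class AgentSpec:
    """A simulated participant.

    ``dwell_min_gain_*`` is the expected extra viewing time (seconds) on the
    larger-minimum option per JPY of dMin. ``first_view_low_bias_*`` is the
    probability that a trial's first inspected cell is the minimum (L) box.
    ``rt_mean_*`` are mean response times (s) of the truncated lognormal RT
    model; deciding for oneself is slower by default, mirroring the typical
    Self > Other response-time gap.
    """

    alpha_self: float = 0.45
    alpha_other: float = 0.45
    lam: float = 0.02
    empathic_concern: float = 3.5
    first_view_low_bias_self: float = 0.75
    first_view_low_bias_other: float = 0.60
    dwell_min_gain_self: float = 0.002
    dwell_min_gain_other: float = 0.0
    dwell_base_bias: float = 0.0  # subject-level dwell-difference offset, s
    rt_mean_self: float = 9.49
    rt_mean_other: float = 8.41
    rt_sigma: float = 0.45
    rt_deadline: float = 30.0

    def alpha(self, condition: str) -> float:
        return self.alpha_self if condition == "Self" else self.alpha_other

    def first_view_low_bias(self, condition: str) -> float:
        return (
            self.first_view_low_bias_self
            if condition == "Self"
            else self.first_view_low_bias_other
        )

    def dwell_min_gain(self, condition: str) -> float:
        return self.dwell_min_gain_self if condition == "Self" else self.dwell_min_gain_other

    def rt_mean(self, condition: str) -> float:
        return self.rt_mean_self if condition == "Self" else self.rt_mean_other

    def params(self, condition: str) -> SubjectParams:
        return SubjectParams(alpha=self.alpha(condition), lam=self.lam)


def fmri_agent(**kw) -> AgentSpec:
    """AgentSpec with scanner-task response-time defaults (5 s deadline)."""
    base = dict(rt_mean_self=2.59, rt_mean_other=2.51, rt_sigma=0.25, rt_deadline=5.0)
    base.update(kw)
    return AgentSpec(**base)


def _draw_rt(n: int, mean: float, sigma: float, deadline: float, rng) -> np.ndarray:
    """Truncated lognormal RTs with the requested (pre-truncation) mean."""
    mu = np.log(mean) - sigma**2 / 2.0
    rt = rng.lognormal(mu, sigma, size=n)
    for _ in range(100):
        bad = rt >= deadline
        if not bad.any():
            break
        rt[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    return np.minimum(rt, deadline * 0.999)


def simulate_choices(
    pairs: list[ChoicePair],
    agent: AgentSpec,
    condition: str,
    rng=None,
) -> list[ChoiceRecord]:
    """Draw one softmax choice + RT per pair under the agent's condition alpha."""
    rng = _rng(rng)
    params = agent.params(condition)
    p_a = np.array([choice_probability(p, params) for p in pairs])
    take_a = rng.random(len(pairs)) < p_a
    rts = _draw_rt(len(pairs), agent.rt_mean(condition), agent.rt_sigma, agent.rt_deadline, rng)
    return [
        ChoiceRecord(
            trial_id=i,
            condition=condition,
            pair=pair,
            choice="a" if take_a[i] else "b",
            rt=float(rts[i]),
        )
        for i, pair in enumerate(pairs)
    ]


def trial_layout(trial_id: int) -> str:
    """Column order of the amount boxes, alternated every 6 trials."""
    return "LMH" if (trial_id // 6) % 2 == 0 else "HML"


# ---------------------------------------------------------------------------
# Mouselab view logs
# ---------------------------------------------------------------------------

def simulate_mouselab(
    records: list[ChoiceRecord],
    agent: AgentSpec,
    condition: str,
    rng=None,
    mean_extra_views: float = 4.0,
    min_views: int = 4,
    view_time_frac: tuple[float, float] = (0.55, 0.8),
    dwell_noise_sd: float = 0.4,
    m_share_first: float = 0.15,
    cell_probs: tuple[float, float, float] = (0.42, 0.16, 0.42),
) -> pd.DataFrame:
    """Generate an ordered, non-overlapping box-view log for each trial.

    Views alternate between the two options (random starting side) so both
    options are always inspected. The first view's cell is L with the
    condition's ``first_view_low_bias``; later cells are drawn independently.
    View durations are scaled so that expected total dwell on the
    larger-minimum option exceeds the other option by
    ``dwell_min_gain * dMin`` seconds, plus Gaussian trial noise.
    """
    rng = _rng(rng)
    n_trials = len(records)
    if n_trials == 0:
        return pd.DataFrame(
            columns=["trial_id", "condition", "option", "cell", "onset_s", "offset_s", "layout"]
        )
    rt = np.array([r.rt for r in records])
    if np.any(rt <= 0):
        raise ValueError("all trials must have positive rt")
    dmin = np.array([r.pair.delta_min for r in records])
    larger_is_a = np.array([r.pair.signed_min_advantage != "b" for r in records])

    n_views = min_views + rng.poisson(mean_extra_views, n_trials)
    total = int(n_views.sum())
    trial_idx = np.repeat(np.arange(n_trials), n_views)
    starts = np.concatenate([[0], np.cumsum(n_views)])[:-1]
    within = np.arange(total) - starts[trial_idx]

    # options strictly alternate from a random starting side
    start_side = rng.integers(0, 2, n_trials)  # 0 -> 'a' first
    opt_bit = (within + start_side[trial_idx]) % 2  # 0 -> 'a'
    option = np.where(opt_bit == 0, "a", "b")

    # cells: biased first view, iid afterwards
    bias = agent.first_view_low_bias(condition)
    u = rng.random(total)
    p_l, p_m = bias, (1.0 - bias) * m_share_first
    first_cell = np.where(u < p_l, "L", np.where(u < p_l + p_m, "M", "H"))
    later_cell = rng.choice(np.array(CELLS), size=total, p=np.asarray(cell_probs))
    cell = np.where(within == 0, first_cell, later_cell)

    # durations: per-(trial, option) gamma weights scaled to dwell targets
    frac = rng.uniform(*view_time_frac, n_trials)
    view_total = frac * rt
    gain = agent.dwell_min_gain(condition)
    d_target = agent.dwell_base_bias + gain * dmin + rng.normal(0.0, dwell_noise_sd, n_trials)
    d_target = np.clip(d_target, -0.8 * view_total, 0.8 * view_total)
    on_larger = opt_bit == (~larger_is_a[trial_idx]).astype(int)
    dwell_target = np.where(
        on_larger,
        (view_total[trial_idx] + d_target[trial_idx]) / 2.0,
        (view_total[trial_idx] - d_target[trial_idx]) / 2.0,
    )
    w = rng.gamma(2.0, 1.0, total)
    group = trial_idx * 2 + opt_bit
    wsum = np.bincount(group, weights=w, minlength=2 * n_trials)
    dur = w / wsum[group] * dwell_target

    # gaps: n_views + 1 Dirichlet slots filling rt - view_total
    g = rng.gamma(1.0, 1.0, total + n_trials)  # one extra slot per trial
    gtrial = np.repeat(np.arange(n_trials), n_views + 1)
    gsum = np.bincount(gtrial, weights=g, minlength=n_trials)
    gaps_all = g / gsum[gtrial] * (rt - view_total)[gtrial]
    # keep the gap preceding each view (drop each trial's final slot)
    keep = np.ones(total + n_trials, dtype=bool)
    keep[np.cumsum(n_views + 1) - 1] = False
    gap = gaps_all[keep]

    step = gap + dur
    cum = np.cumsum(step)
    base = np.concatenate([[0.0], cum[np.cumsum(n_views) - 1][:-1]])
    offset = cum - base[trial_idx]
    onset = offset - dur

    return pd.DataFrame(
        {
            "trial_id": np.array([records[i].trial_id for i in range(n_trials)])[trial_idx],
            "condition": condition,
            "option": option,
            "cell": cell,
            "onset_s": onset,
            "offset_s": offset,
            "layout": [trial_layout(records[i].trial_id) for i in trial_idx],
        }
    )


# ---------------------------------------------------------------------------
# gaze streams
# ---------------------------------------------------------------------------

def _min_jerk(n: int) -> np.ndarray:
    """Minimum-jerk displacement profile on n interior samples (0..1 open)."""
    tau = np.arange(1, n + 1) / (n + 1)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_gaze(
    records: list[ChoiceRecord],
    agent: AgentSpec,
    condition: str,
    layout,
    rng=None,
    rate: float = 500.0,
    jitter_sd: float = 0.2,
    fixation_scatter: float = 0.3,
    saccade_samples: int = 20,
    min_fix_samples: int = 90,
    mean_fixations: float = 5.0,
    dwell_noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Piecewise fixation/saccade gaze streams over the two option AOIs.

    Fixations alternate between the left and right AOI; saccades follow a
    minimum-jerk displacement profile over ``saccade_samples`` samples whose
    peak velocity far exceeds typical classification thresholds. Fixation
    time is allocated so the larger-minimum option receives
    ``dwell_min_gain * dMin`` extra seconds in expectation. Returns
    ``(samples, truth)``: uniformly spaced samples and the ground-truth event
    table (type, onset/offset sample indices and times, AOI).

    With ``jitter_sd = 0`` the trace is noiseless: position is constant
    within each fixation.
    """
    rng = _rng(rng)
    dt = 1.0 / rate
    centers = {"left": layout.left.center, "right": layout.right.center}
    sides = ("left", "right")
    sample_rows = []
    truth_rows = []
    for rec in records:
        n_total = int(np.floor(rec.rt * rate))
        # left/right assignment of options alternates trial to trial
        a_side = sides[rec.trial_id % 2]
        larger_side = a_side if rec.pair.signed_min_advantage != "b" else (
            "right" if a_side == "left" else "left"
        )
        gain = agent.dwell_min_gain(condition)
        d_seconds = (
            agent.dwell_base_bias
            + gain * rec.pair.delta_min
            + rng.normal(0.0, dwell_noise_sd)
        )
        d_samples = d_seconds * rate

        n_fix = max(2, 2 + rng.poisson(max(mean_fixations - 2, 0.1)))
        while n_fix * min_fix_samples + (n_fix - 1) * saccade_samples > n_total and n_fix > 2:
            n_fix -= 1
        fix_budget = n_total - (n_fix - 1) * saccade_samples
        start_side = sides[rng.integers(0, 2)]
        fix_sides = [
            start_side if i % 2 == 0 else ("right" if start_side == "left" else "left")
            for i in range(n_fix)
        ]
        on_larger = np.array([s == larger_side for s in fix_sides])
        d = float(np.clip(d_samples, -0.6 * fix_budget, 0.6 * fix_budget))
        tgt_larger = (fix_budget + d) / 2.0
        tgt_smaller = (fix_budget - d) / 2.0
        w = rng.gamma(3.0, 1.0, n_fix)
        lens = np.empty(n_fix)
        for flag, tgt in ((True, tgt_larger), (False, tgt_smaller)):
            m = on_larger == flag
            if m.any():
                lens[m] = w[m] / w[m].sum() * tgt
        lens = np.maximum(np.round(lens).astype(int), min_fix_samples)
        # absorb rounding drift in the longest fixation
        lens[np.argmax(lens)] += fix_budget - int(lens.sum())
        if lens.min() < min_fix_samples:
            lens = np.full(n_fix, fix_budget // n_fix, dtype=int)
            lens[0] += fix_budget - int(lens.sum())

        fix_centers = []
        for i in range(n_fix):
            cx, cy = centers[fix_sides[i]]
            fix_centers.append(
                (cx + rng.normal(0, fixation_scatter), cy + rng.normal(0, fixation_scatter))
            )
        x = np.empty(n_total)
        y = np.empty(n_total)
        pos = 0
        for i in range(n_fix):
            cx, cy = fix_centers[i]
            seg = int(lens[i])
            x[pos : pos + seg] = cx
            y[pos : pos + seg] = cy
            truth_rows.append(
                {
                    "trial_id": rec.trial_id,
                    "type": "fixation",
                    "onset_idx": pos,
                    "offset_idx": pos + seg,
                    "aoi": fix_sides[i],
                }
            )
            pos += seg
            if i < n_fix - 1:
                nx, ny = fix_centers[i + 1]
                prof = _min_jerk(saccade_samples)
                x[pos : pos + saccade_samples] = cx + (nx - cx) * prof
                y[pos : pos + saccade_samples] = cy + (ny - cy) * prof
                truth_rows.append(
                    {
                        "trial_id": rec.trial_id,
                        "type": "saccade",
                        "onset_idx": pos,
                        "offset_idx": pos + saccade_samples,
                        "aoi": "none",
                    }
                )
                pos += saccade_samples
        if jitter_sd > 0:
            # fixational jitter is slow tremor/drift, not white noise: white
            # noise of this amplitude at 500 Hz would alone exceed saccade
            # velocity thresholds. Low-pass filtered noise (200 ms window)
            # scaled to sd jitter_sd, plus small white measurement noise.
            win = 100
            for arr in (x, y):
                w = rng.normal(0.0, 1.0, n_total + win - 1)
                drift = np.convolve(w, np.ones(win) / win, mode="valid")
                arr += drift * (jitter_sd * np.sqrt(win))
                arr += rng.normal(0.0, jitter_sd / 10.0, n_total)
        t = np.arange(n_total) * dt
        sample_rows.append(
            pd.DataFrame(
                {
                    "trial_id": rec.trial_id,
                    "t_s": t,
                    "x_deg": x,
                    "y_deg": y,
                    "valid": True,
                }
            )
        )
    samples = pd.concat(sample_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    truth["onset_s"] = truth["onset_idx"] * dt
    truth["offset_s"] = truth["offset_idx"] * dt
    return samples, truth


# ---------------------------------------------------------------------------
# BOLD / event schedules
# ---------------------------------------------------------------------------

def make_event_schedule(
    records_by_condition: dict[str, list[ChoiceRecord]],
    rng=None,
    block_len: int = 12,
    cue_duration: float = 1.0,
    soa_choices: tuple[float, ...] = (2.0, 4.0, 6.0),
    iti_choices: tuple[float, ...] = (2.0, 4.0, 6.0),
    alpha_by_condition: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Event table for one scanning run of the choice task.

    Trials run in alternating blocks of ``block_len`` per condition. Each
    trial contributes a 1 s cue event, a choice event whose duration is that
    trial's response time (carrying dMin / dEV and, when condition-mean
    maximin weights are supplied, dU modulators), and a zero-duration
    response event.
    """
    from .core import delta_u

    rng = _rng(rng)
    conds = list(records_by_condition)
    queues = {c: list(records_by_condition[c]) for c in conds}
    order: list[tuple[str, ChoiceRecord]] = []
    ci = 0
    while any(queues.values()):
        c = conds[ci % len(conds)]
        take, queues[c] = queues[c][:block_len], queues[c][block_len:]
        order.extend((c, r) for r in take)
        ci += 1
    rows = []
    t = float(rng.choice(iti_choices))
    for cond, rec in order:
        rows.append({"onset": t, "duration": cue_duration, "trial_type": "cue"})
        t += cue_duration + float(rng.choice(soa_choices))
        row = {
            "onset": t,
            "duration": rec.rt,
            "trial_type": cond,
            "dmin": rec.pair.delta_min,
            "dev": rec.pair.delta_ev,
        }
        if alpha_by_condition is not None:
            row["du"] = delta_u(rec.pair, alpha_by_condition[cond])
        rows.append(row)
        rows.append({"onset": t + rec.rt, "duration": 0.0, "trial_type": "response"})
        t += 5.0 + float(rng.choice(iti_choices))
    return pd.DataFrame(rows)


def simulate_bold(design, betas, noise_sd: float, rng=None) -> np.ndarray:
    """BOLD series y = X @ beta + N(0, noise_sd)."""
    rng = _rng(rng)
    X = design.values if isinstance(design, pd.DataFrame) else np.asarray(design)
    betas = np.asarray(betas, dtype=float)
    if X.shape[1] != betas.shape[0]:
        raise ValueError(f"design has {X.shape[1]} columns but {betas.shape[0]} betas given")
    y = X @ betas
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=X.shape[0])
    return y


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Population distributions for cohort simulation.

    The latent maximin weight has a Beta-distributed subject mean; the
    Other-minus-Self contrast ``delta`` and the empathic-concern score are
    linked through a Gaussian copula with correlation ``rho``.
    """

    n_subjects: int = 60
    alpha_mean: float = 0.45
    alpha_sd: float = 0.15
    delta_sd: float = 0.15
    rho: float = 0.4
    empathy_mean: float = 3.5
    empathy_sd: float = 0.8
    lam: float = 0.02
    first_view_low_bias_self: float = 0.75
    first_view_low_bias_other: float = 0.60
    first_view_logit_sd: float = 0.5
    dwell_min_gain_self: float = 0.002
    dwell_min_gain_other: float = 0.0
    dwell_bias_sd: float = 0.15
    design: DesignConfig = field(default_factory=DesignConfig)

    def beta_params(self) -> tuple[float, float]:
        m, v = self.alpha_mean, self.alpha_sd**2
        k = m * (1 - m) / v - 1
        if k <= 0:
            raise ValueError("alpha_sd too large for a Beta distribution")
        return m * k, (1 - m) * k


def draw_agents(pop: PopulationConfig, rng=None) -> list[AgentSpec]:
    """Draw per-subject AgentSpecs from the population model."""
    rng = _rng(rng)
    n = pop.n_subjects
    cov = np.array([[1.0, pop.rho], [pop.rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    empathy = np.clip(pop.empathy_mean + pop.empathy_sd * z[:, 0], 1.0, 7.0)
    delta = pop.delta_sd * z[:, 1]  # alpha_other - alpha_self
    a, b = pop.beta_params()
    mid = rng.beta(a, b, n)
    alpha_self = np.clip(mid - delta / 2.0, 0.0, 1.0)
    alpha_other = np.clip(mid + delta / 2.0, 0.0, 1.0)

    def expit(v):
        return 1.0 / (1.0 + np.exp(-v))

    def logit(p):
        return np.log(p / (1.0 - p))

    # one search-propensity deviate per subject, shared across conditions, so
    # the condition contrast is a fixed effect over a subject random intercept
    fv_jit = rng.normal(0, pop.first_view_logit_sd, n)
    fv_self = expit(logit(pop.first_view_low_bias_self) + fv_jit)
    fv_other = expit(logit(pop.first_view_low_bias_other) + fv_jit)
    dwell_bias = rng.normal(0.0, pop.dwell_bias_sd, n)
    return [
        AgentSpec(
            alpha_self=float(alpha_self[i]),
            alpha_other=float(alpha_other[i]),
            lam=pop.lam,
            empathic_concern=float(empathy[i]),
            first_view_low_bias_self=float(fv_self[i]),
            first_view_low_bias_other=float(fv_other[i]),
            dwell_min_gain_self=pop.dwell_min_gain_self,
            dwell_min_gain_other=pop.dwell_min_gain_other,
            dwell_base_bias=float(dwell_bias[i]),
        )
        for i in range(n)
    ]


def simulate_cohort(
    pop: PopulationConfig | None = None,
    rng=None,
    include_views: bool = False,
) -> dict[str, pd.DataFrame]:
    """Full synthetic cohort: per-subject truth, choices, optional view logs.

    Returns a dict with ``truth`` (one row per subject: generating
    parameters and empathy score), ``choices`` (long trial table in the
    choices.tsv schema plus subject_id), and, when requested, ``views``.
    """
    pop = pop or PopulationConfig()
    rng = _rng(rng)
    if pop.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    pairs = generate_lottery_set(pop.design, rng)
    agents = draw_agents(pop, rng)
    truth = pd.DataFrame(
        {
            "subject_id": np.arange(pop.n_subjects),
            "alpha_self": [a.alpha_self for a in agents],
            "alpha_other": [a.alpha_other for a in agents],
            "lam": [a.lam for a in agents],
            "empathic_concern": [a.empathic_concern for a in agents],
        }
    )
    choice_frames = []
    view_frames = []
    for sid, agent in enumerate(agents):
        for cond in ("Self", "Other"):
            recs = simulate_choices(pairs, agent, cond, rng)
            df = records_to_frame(recs)
            df.insert(0, "subject_id", sid)
            choice_frames.append(df)
            if include_views:
                v = simulate_mouselab(recs, agent, cond, rng)
                v.insert(0, "subject_id", sid)
                view_frames.append(v)
    out = {"truth": truth, "choices": pd.concat(choice_frames, ignore_index=True)}
    if include_views:
        out["views"] = pd.concat(view_frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# record <-> frame conversion (choices.tsv schema)
# ---------------------------------------------------------------------------

def records_to_frame(records: list[ChoiceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        a = sorted(r.pair.option_a.outcomes)
        b = sorted(r.pair.option_b.outcomes)
        rows.append(
            {
                "trial_id": r.trial_id,
                "condition": r.condition,
                "a_low": a[0],
                "a_mid": a[1],
                "a_high": a[2],
                "b_low": b[0],
                "b_mid": b[1],
                "b_high": b[2],
                "choice": r.choice,
                "rt_s": r.rt,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ChoiceRecord]:
    records = []
    for row in df.itertuples(index=False):
        pair = ChoicePair(
            Lottery((float(row.a_low), float(row.a_mid), float(row.a_high))),
            Lottery((float(row.b_low), float(row.b_mid), float(row.b_high))),
        )
        records.append(
            ChoiceRecord(
                trial_id=int(row.trial_id),
                condition=str(row.condition),
                pair=pair,
                choice=str(row.choice),
                rt=float(row.rt_s),
            )
        )
    return records
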