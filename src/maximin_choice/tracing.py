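"""Mouselab information-search analysis.

Operates on long-format view-event tables (one row per box view) with columns
``trial_id, subject_id, condition, option, cell, onset_s, offset_s, layout``:
quartile view shares over the decision time, first-view bias (L vs H, first
views on M excluded) with a random-intercept logistic mixed model, and a
linear mixed model of per-trial dwell differences between the larger- and
smaller-minimum options on dMin and dEV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mixed import MixedLogitResult, fit_logit_mixed

CELLS = ("L", "M", "H")


# ---------------------------------------------------------------------------
# quartile view shares
# ---------------------------------------------------------------------------

def trial_quartile_shares(views: pd.DataFrame, decision_time: float) -> np.ndarray:
    """(4, 3) percentage of viewing time on L/M/H per decision-time quartile.

    The decision time is split into four equal sub-intervals and each view's
    duration is apportioned by exact overlap; within a quartile with any
    viewing the three shares sum to 100. Quartiles with no viewing are NaN.
    """
    if decision_time <= 0:
        raise ValueError("decision time must be positive")
    if len(views) == 0:
        raise ValueError("trial has no view events")
    bounds = np.linspace(0.0, decision_time, 5)
    dur = np.zeros((4, 3))
    cell_idx = {c: i for i, c in enumerate(CELLS)}
    on = views["onset_s"].to_numpy(dtype=float)
    off = views["offset_s"].to_numpy(dtype=float)
    ci = views["cell"].map(cell_idx).to_numpy()
    for q in range(4):
        overlap = np.clip(np.minimum(off, bounds[q + 1]) - np.maximum(on, bounds[q]), 0.0, None)
        np.add.at(dur[q], ci, overlap)
    total = dur.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(total > 0, dur / total * 100.0, np.nan)
    return shares


def quartile_view_shares(
    views: pd.DataFrame,
    decision_times: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Average quartile shares per subject and condition (trials first).

    ``decision_times``, if given, maps (subject_id, trial_id) to rt_s; by
    default each trial's decision time is its last view offset. Returns a
    long table: subject_id, condition, quartile (1-4), cell, share_pct.
    """
    dt_map = None
    if decision_times is not None:
        dt_map = decision_times.set_index(["subject_id", "condition", "trial_id"])["rt_s"]
    rows = []
    for (sid, cond), grp in views.groupby(["subject_id", "condition"]):
        per_trial = []
        for tid, tv in grp.groupby("trial_id"):
            T = (
                float(dt_map.loc[(sid, cond, tid)])
                if dt_map is not None
                else float(tv["offset_s"].max())
            )
            per_trial.append(trial_quartile_shares(tv, T))
        mean_shares = np.nanmean(np.stack(per_trial), axis=0)
        for q in range(4):
            for c, cell in enumerate(CELLS):
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": cond,
                        "quartile": q + 1,
                        "cell": cell,
                        "share_pct": mean_shares[q, c],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# first views
# ---------------------------------------------------------------------------

def first_view_trials(views: pd.DataFrame) -> pd.DataFrame:
    """One row per trial: the first-viewed cell, with M-first trials flagged.

    Returns columns subject_id, condition, trial_id, layout, first_cell and
    ``first_is_low`` (1 = L, 0 = H, NaN = M, excluded from modeling).
    """
    first = (
        views.sort_values("onset_s")
        .groupby(["subject_id", "condition", "trial_id"], as_index=False)
        .first()[["subject_id", "condition", "trial_id", "layout", "cell"]]
        .rename(columns={"cell": "first_cell"})
    )
    first["first_is_low"] = np.where(
        first["first_cell"] == "L", 1.0, np.where(first["first_cell"] == "H", 0.0, np.nan)
    )
    return first


def first_view_counts(views: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition counts of first views on L and H (M excluded,
    but reported)."""
    first = first_view_trials(views)
    out = (
        first.assign(
            n_first_L=(first["first_cell"] == "L").astype(int),
            n_first_H=(first["first_cell"] == "H").astype(int),
            n_excluded_M=(first["first_cell"] == "M").astype(int),
        )
        .groupby(["subject_id", "condition"], as_index=False)[
            ["n_first_L", "n_first_H", "n_excluded_M"]
        ]
        .sum()
    )
    return out


def fit_first_view_model(views: pd.DataFrame) -> MixedLogitResult:
    """Random-intercept logistic model of P(first view = L).

    Fixed effects: intercept, condition (Self = 1, Other = 0) and layout
    dummy (HML = 1). Subjects are random intercepts; estimation is
    Gauss-Hermite maximum likelihood with Wald z statistics.
    """
    first = first_view_trials(views).dropna(subset=["first_is_low"])
    if first["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if first["condition"].nunique() < 2:
        raise ValueError("both conditions must be present")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "cond_self": (first["condition"] == "Self").astype(float),
            "layout_hml": (first["layout"] == "HML").astype(float),
        }
    )
    return fit_logit_mixed(first["first_is_low"].to_numpy(), X, first["subject_id"].to_numpy())


# ---------------------------------------------------------------------------
# dwell differences
# ---------------------------------------------------------------------------

def dwell_difference_table(views: pd.DataFrame, choices: pd.DataFrame) -> pd.DataFrame:
    """Per-trial dwell difference (larger-min option minus smaller-min).

    ``choices`` supplies the lottery amounts per (subject_id, condition,
    trial_id) in the choices.tsv schema. Positive values mean more viewing of
    the option holding the larger minimum; tied-minimum trials are dropped.
    """
    views = views.assign(dur=views["offset_s"] - views["onset_s"])
    dwell = (
        views.groupby(["subject_id", "condition", "trial_id", "option"])["dur"]
        .sum()
        .unstack("option", fill_value=0.0)
        .reset_index()
    )
    for col in ("a", "b"):
        if col not in dwell:
            dwell[col] = 0.0
    merged = dwell.merge(choices, on=["subject_id", "condition", "trial_id"], how="inner")
    merged = merged[merged["a_low"] != merged["b_low"]].copy()
    larger_a = merged["a_low"] > merged["b_low"]
    merged["dwell_diff"] = np.where(larger_a, merged["a"] - merged["b"], merged["b"] - merged["a"])
    merged["dmin"] = (merged["a_low"] - merged["b_low"]).abs()
    ev_a = merged[["a_low", "a_mid", "a_high"]].mean(axis=1)
    ev_b = merged[["b_low", "b_mid", "b_high"]].mean(axis=1)
    merged["dev"] = (ev_a - ev_b).abs()
    layout = views.groupby(["subject_id", "condition", "trial_id"])["layout"].first().reset_index()
    merged = merged.merge(layout, on=["subject_id", "condition", "trial_id"], how="left")
    return merged[
        ["subject_id", "condition", "trial_id", "dwell_diff", "dmin", "dev", "layout"]
    ]


def dwell_difference_model(table: pd.DataFrame) -> pd.DataFrame:
    """Random-intercept linear mixed model of dwell_diff on dMin, dEV, layout.

    Fit separately per condition with statsmodels MixedLM (REML); p-values
    are Wald, using the normal approximation. Returns a tidy coefficient
    table (condition, term, coef, se, z, p).
    """
    import statsmodels.formula.api as smf

    if table["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for cond, grp in table.groupby("condition"):
        if grp["dmin"].nunique() < 2:
            raise ValueError(f"dMin is constant in condition {cond}; slope unidentifiable")
        grp = grp.assign(layout_hml=(grp["layout"] == "HML").astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "dwell_diff ~ dmin + dev + layout_hml", grp, groups=grp["subject_id"]
            )
            fit = model.fit(method="lbfgs", reml=True)
        for term in ("Intercept", "dmin", "dev", "layout_hml"):
            rows.append(
                {
                    "condition": cond,
                    "term": term,
                    "coef": fit.params[term],
                    "se": fit.bse[term],
                    "z": fit.params[term] / fit.bse[term],
                    "p": fit.pvalues[term],
                }
            )
    return pd.DataFrame(rows)
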