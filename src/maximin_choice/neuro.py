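"""Model-based fMRI design construction on 1-D ROI series.

Builds first-level design matrices for the choice task: condition boxcars
whose durations are the trial response times, a 1 s cue regressor, a
zero-duration response regressor, and parametric modulators — dU under GLM1,
dMin and dEV under GLM2 — mean-centered within condition before convolution
with the canonical double-gamma hemodynamic response function. Discrete-
cosine high-pass columns (128 s cutoff) and an intercept complete the
matrix. Also provides OLS estimation, ROI eigenvariate extraction, and
generalized psychophysiological-interaction (gPPI) regressors formed at the
BOLD level (centered seed x convolved, centered condition regressor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

CHOICE_CONDITIONS = ("Self", "Other", "Comp")
MODULATORS = {"GLM1": ("du",), "GLM2": ("dmin", "dev")}


def hrf_kernel(tr: float, oversampling: int = 16, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at tr / oversampling, peak = 1.

    Response gamma peaks at 6 s, undershoot at 16 s, peak:undershoot ratio 6.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, length, dt)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift columns for periods longer than ``cutoff`` s."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_scans))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    tr: float,
    n_scans: int,
    hrf: np.ndarray,
    oversampling: int,
) -> np.ndarray:
    """Boxcar (or stick for zero durations) at microtime resolution,
    convolved with the HRF and sampled at the middle microtime bin of each
    TR."""
    dt = tr / oversampling
    n_bins = n_scans * oversampling
    u = np.zeros(n_bins)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(on / dt))
        if i0 >= n_bins:
            continue
        if dur <= 0:
            u[i0] += amp
        else:
            i1 = min(int(np.round((on + dur) / dt)), n_bins)
            u[i0:i1] += amp
    x = np.convolve(u, hrf)[:n_bins]
    return x[oversampling // 2 :: oversampling][:n_scans]


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    model: str | None = None,
    oversampling: int = 16,
    hpf_cutoff: float | None = 128.0,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """First-level design matrix from a BIDS-like event table.

    ``events`` needs onset, duration, trial_type, plus modulator columns
    (du for GLM1; dmin and dev for GLM2) on choice-condition rows.
    Modulators are mean-centered within condition before convolution, so a
    constant modulator yields an identically-zero column.
    """
    end = (events["onset"] + events["duration"]).max()
    if end > n_scans * tr:
        bad = events[(events["onset"] + events["duration"]) > n_scans * tr]
        raise ValueError(
            f"{len(bad)} event(s) extend beyond the scan window "
            f"({n_scans * tr:.1f} s): onsets {bad['onset'].tolist()[:5]}"
        )
    hrf = hrf_kernel(tr, oversampling)
    cols: dict[str, np.ndarray] = {}
    present = [c for c in (*CHOICE_CONDITIONS, "cue", "response")
               if (events["trial_type"] == c).any()]
    mods = MODULATORS.get(model, ()) if model else ()
    if model and model not in MODULATORS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODULATORS)}")
    for cond in present:
        ev = events[events["trial_type"] == cond]
        on = ev["onset"].to_numpy(dtype=float)
        dur = ev["duration"].to_numpy(dtype=float)
        cols[cond] = _convolved_regressor(
            on, dur, np.ones(len(ev)), tr, n_scans, hrf, oversampling
        )
        if cond in CHOICE_CONDITIONS:
            for mod in mods:
                if mod not in ev or ev[mod].isna().any():
                    raise ValueError(f"modulator {mod!r} missing for condition {cond}")
                vals = ev[mod].to_numpy(dtype=float)
                centered = vals - vals.mean()
                cols[f"{cond}_x_{mod}"] = _convolved_regressor(
                    on, dur, centered, tr, n_scans, hrf, oversampling
                )
    X = pd.DataFrame(cols)
    if hpf_cutoff is not None:
        hp = dct_highpass_basis(n_scans, tr, hpf_cutoff)
        for k in range(hp.shape[1]):
            X[f"hpf_{k + 1}"] = hp[:, k]
    if add_intercept:
        X["intercept"] = 1.0
    X.index.name = "scan"
    return X


@dataclass
class GLMResult:
    params: pd.Series
    se: pd.Series
    tstats: pd.Series
    pvalues: pd.Series
    df_resid: int
    sigma2: float
    residuals: np.ndarray


def fit_glm(bold: np.ndarray, design: pd.DataFrame) -> GLMResult:
    """Ordinary least squares with classical t statistics."""
    X = design.to_numpy(dtype=float)
    y = np.asarray(bold, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("BOLD length must equal design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"design is rank deficient; collinear columns include {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = y.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid / df)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tstat = beta / se
    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    idx = design.columns
    return GLMResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tstats=pd.Series(tstat, index=idx),
        pvalues=pd.Series(p, index=idx),
        df_resid=df,
        sigma2=sigma2,
        residuals=resid,
    )


def roi_eigenvariate(series: np.ndarray) -> np.ndarray:
    """First eigenvariate of a (time x voxel) matrix.

    Columns are mean-centered; the first left singular vector is scaled by
    s1 / sqrt(n_voxels) and sign-aligned with the ROI mean series, so a
    single-voxel ROI returns its own centered series.
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] < 1:
        raise ValueError("need at least one voxel series")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    if not np.any(Yc):
        raise ValueError("zero-variance ROI input")
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    e = U[:, 0] * S[0] / np.sqrt(Y.shape[1])
    mean_series = Yc.mean(axis=1)
    if e @ mean_series < 0:
        e = -e
    return e


def gppi_design(
    seed: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    interaction_conditions: tuple[str, ...] = ("Self", "Other"),
    oversampling: int = 16,
    hpf_cutoff: float | None = 128.0,
) -> pd.DataFrame:
    """Task regressors + centered seed + per-condition interaction columns.

    Interactions are formed at the BOLD level: ppi_<cond> = centered seed
    series x the condition's HRF-convolved, centered regressor. Regressing a
    target ROI series on this design gives the interaction betas used as
    condition-specific connectivity estimates.
    """
    seed = np.asarray(seed, dtype=float)
    if seed.shape[0] != n_scans:
        raise ValueError("seed series length must equal n_scans")
    X = build_design(events, tr, n_scans, model=None,
                     oversampling=oversampling, hpf_cutoff=hpf_cutoff)
    seed_c = seed - seed.mean()
    out = {}
    task_cols = [c for c in X.columns if not c.startswith("hpf_") and c != "intercept"]
    for c in task_cols:
        out[c] = X[c].to_numpy()
    out["seed"] = seed_c
    for cond in interaction_conditions:
        if cond not in X.columns:
            raise ValueError(f"condition {cond!r} not present in events")
        reg = X[cond].to_numpy()
        out[f"ppi_{cond}"] = seed_c * (reg - reg.mean())
    D = pd.DataFrame(out)
    for c in X.columns:
        if c.startswith("hpf_"):
            D[c] = X[c].to_numpy()
    D["intercept"] = 1.0
    return D
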