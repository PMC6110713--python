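"""Group-level inference: t tests, robust percentage-bend correlation,
2x2 repeated-measures ANOVA, and Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; t statistic undefined")
    t, p = sps.ttest_1samp(x, mu0)
    return TestResult(float(t), float(x.size - 1), float(p))


def paired_t(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


def _pb_omega(x: np.ndarray, bend: float) -> float:
    """(1 - bend) quantile of absolute deviations from the median."""
    w = np.sort(np.abs(x - np.median(x)))
    m = int(np.floor((1.0 - bend) * x.size + 0.5))
    return float(w[m - 1])


def _pb_location(x: np.ndarray, bend: float) -> float:
    """Percentage-bend measure of location."""
    omega = _pb_omega(x, bend)
    if omega <= 0:
        raise ValueError("input is (nearly) constant; percentage-bend scale is zero")
    psi = (x - np.median(x)) / omega
    i1 = int(np.sum(psi < -1))
    i2 = int(np.sum(psi > 1))
    sx = np.where(np.abs(psi) > 1, 0.0, x)
    return (np.sum(sx) + omega * (i2 - i1)) / (x.size - i1 - i2)


def pb_correlation(x, y, bend: float = 0.2) -> tuple[float, float, float]:
    """Percentage-bend correlation coefficient with its t test.

    Deviations from a robust location estimate are scaled by the (1 - bend)
    quantile of absolute deviations from the median and winsorized at +-1
    before correlating, which bounds the influence of marginal outliers.
    Returns (r, t, p) with t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length samples with at least 4 observations")
    if not 0.0 < bend < 0.5:
        raise ValueError("bend must lie in (0, 0.5)")
    a = np.clip((x - _pb_location(x, bend)) / _pb_omega(x, bend), -1.0, 1.0)
    b = np.clip((y - _pb_location(y, bend)) / _pb_omega(y, bend), -1.0, 1.0)
    r = float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))
    n = x.size
    if abs(r) >= 1.0:
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(t), float(p)


def rm_anova_2x2(cells) -> dict[str, TestResult]:
    """Two-way fully within-subject ANOVA on an (n, 4) matrix.

    Columns are ordered (A1B1, A1B2, A2B1, A2B2). Each effect in a 2x2
    within design is a single-df contrast, so F = t^2 of the paired t test on
    the corresponding per-subject contrast, with df (1, n - 1). Returns
    TestResults keyed 'A', 'B', 'AxB'.
    """
    c = np.asarray(cells, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise ValueError("cells must be an (n, 4) matrix")
    if np.isnan(c).any():
        raise ValueError("missing cells are not allowed")
    n = c.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    contrasts = {
        "A": (c[:, 0] + c[:, 1] - c[:, 2] - c[:, 3]) / 2.0,
        "B": (c[:, 0] - c[:, 1] + c[:, 2] - c[:, 3]) / 2.0,
        "AxB": c[:, 0] - c[:, 1] - c[:, 2] + c[:, 3],
    }
    out = {}
    for name, d in contrasts.items():
        t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(n))
        F = t * t
        p = float(sps.f.sf(F, 1, n - 1))
        out[name] = TestResult(float(F), float(n - 1), p)
    return out


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def cohens_d(x, y=None) -> float:
    """Cohen's d for one sample (vs 0) or a paired difference."""
    d = np.asarray(x, dtype=float) if y is None else np.asarray(x) - np.asarray(y)
    return float(np.mean(d) / np.std(d, ddof=1))
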