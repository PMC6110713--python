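"""Velocity/acceleration-threshold gaze-event classification and option-AOI
dwell analysis.

Raw gaze samples (nominally 500 Hz) are smoothed with a short moving
average; speed and its rate of change are computed by central finite
differences. A sample belongs to a saccade when speed exceeds the velocity
threshold (default 30 deg/s) or |acceleration| exceeds the acceleration
threshold (default 9500 deg/s^2); maximal runs of non-saccade samples lasting
at least the minimum fixation duration (default 100 ms) become fixations.
Fixations are then assigned to the left / right lottery-option areas of
interest by centroid and summed into per-option dwell times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ChoiceRecord


@dataclass(frozen=True)
class EventThresholds:
    saccade_velocity: float = 30.0  # deg/s
    saccade_acceleration: float = 9500.0  # deg/s^2
    min_fixation: float = 0.100  # s

    def __post_init__(self) -> None:
        if min(self.saccade_velocity, self.saccade_acceleration, self.min_fixation) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("rectangle must have positive extent")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


def _overlaps(a: Rect, b: Rect) -> bool:
    return not (a.x1 < b.x0 or b.x1 < a.x0 or a.y1 < b.y0 or b.y1 < a.y0)


@dataclass(frozen=True)
class Layout:
    """Two non-overlapping option AOIs (degrees of visual angle)."""

    left: Rect = field(default_factory=lambda: Rect(-8.0, -3.0, -2.0, 3.0))
    right: Rect = field(default_factory=lambda: Rect(2.0, -3.0, 8.0, 3.0))

    def __post_init__(self) -> None:
        if _overlaps(self.left, self.right):
            raise ValueError("option AOIs must not overlap")

    @classmethod
    def from_dict(cls, d: dict) -> "Layout":
        return cls(left=Rect(*d["left"]), right=Rect(*d["right"]))


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or v.size < window:
        return v
    pad = window // 2
    vp = np.pad(v, pad, mode="reflect")
    return np.convolve(vp, np.ones(window) / window, mode="valid")


def _central_diff(v: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    return d


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def classify_events(
    samples: pd.DataFrame,
    thresholds: EventThresholds | None = None,
    smooth_window: int = 5,
    max_gap: float = 0.075,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify one trial's gaze samples into fixations and saccades.

    ``samples`` needs columns t_s, x_deg, y_deg and optionally valid. Invalid
    gaps longer than ``max_gap`` split the trace into independently
    classified segments; shorter invalid gaps are linearly interpolated.
    Returns (fixations, saccades) DataFrames with onset_s / offset_s /
    onset_idx / offset_idx (half-open sample ranges) and fixation centroids.
    """
    thresholds = thresholds or EventThresholds()
    t = samples["t_s"].to_numpy(dtype=float)
    x = samples["x_deg"].to_numpy(dtype=float).copy()
    y = samples["y_deg"].to_numpy(dtype=float).copy()
    valid = (
        samples["valid"].to_numpy(dtype=bool)
        if "valid" in samples
        else np.ones_like(t, dtype=bool)
    )
    empty = pd.DataFrame(
        columns=["onset_s", "offset_s", "onset_idx", "offset_idx", "centroid_x", "centroid_y"]
    )
    if valid.sum() < 3:
        warnings.warn("fewer than 3 valid samples; no events classified")
        return empty.copy(), empty.copy()
    dt = float(np.median(np.diff(t)))

    # interpolate short invalid gaps; long gaps become segment boundaries
    segment_breaks = np.zeros(t.size, dtype=bool)
    for s0, s1 in _runs(~valid):
        if (s1 - s0) * dt <= max_gap and s0 > 0 and s1 < t.size:
            for arr in (x, y):
                arr[s0:s1] = np.interp(t[s0:s1], [t[s0 - 1], t[s1]], [arr[s0 - 1], arr[s1]])
        else:
            segment_breaks[s0:s1] = True

    fix_rows, sac_rows = [], []
    for seg0, seg1 in _runs(~segment_breaks):
        if seg1 - seg0 < 3:
            continue
        xs = _smooth(x[seg0:seg1], smooth_window)
        ys = _smooth(y[seg0:seg1], smooth_window)
        vx = _central_diff(xs, dt)
        vy = _central_diff(ys, dt)
        speed = np.hypot(vx, vy)
        accel = _central_diff(speed, dt)
        sacc = (speed > thresholds.saccade_velocity) | (
            np.abs(accel) > thresholds.saccade_acceleration
        )
        for r0, r1 in _runs(sacc):
            sac_rows.append(
                {
                    "onset_s": t[seg0 + r0],
                    "offset_s": t[seg0 + r1 - 1] + dt,
                    "onset_idx": seg0 + r0,
                    "offset_idx": seg0 + r1,
                    "centroid_x": float(np.mean(x[seg0 + r0 : seg0 + r1])),
                    "centroid_y": float(np.mean(y[seg0 + r0 : seg0 + r1])),
                }
            )
        for r0, r1 in _runs(~sacc):
            if (r1 - r0) * dt >= thresholds.min_fixation:
                fix_rows.append(
                    {
                        "onset_s": t[seg0 + r0],
                        "offset_s": t[seg0 + r1 - 1] + dt,
                        "onset_idx": seg0 + r0,
                        "offset_idx": seg0 + r1,
                        "centroid_x": float(np.mean(x[seg0 + r0 : seg0 + r1])),
                        "centroid_y": float(np.mean(y[seg0 + r0 : seg0 + r1])),
                    }
                )
    fixations = pd.DataFrame(fix_rows) if fix_rows else empty.copy()
    saccades = pd.DataFrame(sac_rows) if sac_rows else empty.copy()
    if len(fixations):
        fixations = fixations.sort_values("onset_idx").reset_index(drop=True)
    if len(saccades):
        saccades = saccades.sort_values("onset_idx").reset_index(drop=True)
    return fixations, saccades


def assign_aoi(fixations: pd.DataFrame, layout: Layout) -> pd.DataFrame:
    """Label each fixation with the AOI containing its centroid ('left',
    'right', or 'none')."""
    out = fixations.copy()

    def label(row) -> str:
        if layout.left.contains(row["centroid_x"], row["centroid_y"]):
            return "left"
        if layout.right.contains(row["centroid_x"], row["centroid_y"]):
            return "right"
        return "none"

    out["aoi"] = [label(r) for _, r in out.iterrows()] if len(out) else []
    return out


@dataclass
class OptionDwell:
    dwell_larger_min: float
    dwell_smaller_min: float
    excluded: bool = False

    @property
    def difference(self) -> float:
        return self.dwell_larger_min - self.dwell_smaller_min


def option_dwell(
    fixations: pd.DataFrame,
    trial: ChoiceRecord,
    a_side: str,
    window: tuple[float, float] | None = None,
) -> OptionDwell:
    """Per-option fixation dwell within the option-onset-to-response window.

    ``a_side`` says which AOI ('left'/'right') held option A. Trials with
    tied minima have no larger-minimum option and are flagged excluded.
    """
    if a_side not in ("left", "right"):
        raise ValueError("a_side must be 'left' or 'right'")
    if trial.pair.signed_min_advantage is None:
        return OptionDwell(np.nan, np.nan, excluded=True)
    lo, hi = window if window is not None else (0.0, trial.rt)
    dwell = {"left": 0.0, "right": 0.0}
    for _, f in fixations.iterrows():
        if f.get("aoi", "none") not in dwell:
            continue
        dwell[f["aoi"]] += max(0.0, min(f["offset_s"], hi) - max(f["onset_s"], lo))
    larger_opt = trial.pair.signed_min_advantage
    larger_side = a_side if larger_opt == "a" else ("right" if a_side == "left" else "left")
    smaller_side = "right" if larger_side == "left" else "left"
    return OptionDwell(dwell[larger_side], dwell[smaller_side])
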