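"""Quasi-maximin utility model for three-outcome lotteries and its estimation.

A lottery pays one of three equiprobable monetary outcomes. The utility a
decision maker assigns to lottery ``x`` is a convex combination of its worst
outcome and its expected value,

    U(x) = alpha * min(x) + (1 - alpha) * EV(x),

where ``alpha`` in [0, 1] is the *maximin weight*: alpha = 0 is pure
risk-neutral EV maximization, alpha = 1 pure maximin. Binary choices between
two lotteries follow a logit (softmax) rule with sensitivity ``lam`` (units
1/JPY), and (alpha, lam) are estimated per subject and condition by maximum
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

CONDITIONS = ("Self", "Other", "Comp")


@dataclass(frozen=True)
class Lottery:
    """Three equiprobable monetary outcomes (JPY)."""

    outcomes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.outcomes) != 3:
            raise ValueError("a lottery has exactly three outcomes")
        arr = np.asarray(self.outcomes, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("outcomes must be finite and non-negative")
        object.__setattr__(self, "outcomes", tuple(float(v) for v in self.outcomes))

    @property
    def minimum(self) -> float:
        return min(self.outcomes)

    @property
    def ev(self) -> float:
        return sum(self.outcomes) / 3.0


@dataclass(frozen=True)
class ChoicePair:
    """Two lotteries presented together, with derived trial-level parameters.

    ``delta_min`` and ``delta_ev`` are the absolute between-option differences
    in minimum outcome and expected value; ``signed_min_advantage`` names the
    option holding the larger minimum ('a', 'b', or None for a tie).
    """

    option_a: Lottery
    option_b: Lottery

    @property
    def delta_min(self) -> float:
        return abs(self.option_a.minimum - self.option_b.minimum)

    @property
    def delta_ev(self) -> float:
        return abs(self.option_a.ev - self.option_b.ev)

    @property
    def signed_min_advantage(self) -> str | None:
        da = self.option_a.minimum - self.option_b.minimum
        if da > 0:
            return "a"
        if da < 0:
            return "b"
        return None


@dataclass(frozen=True)
class SubjectParams:
    """Maximin weight alpha in [0, 1] and softmax sensitivity lam (1/JPY)."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")


@dataclass(frozen=True)
class ChoiceRecord:
    trial_id: int
    condition: str
    pair: ChoicePair
    choice: str  # 'a' or 'b'
    rt: float  # seconds

    def __post_init__(self) -> None:
        if self.choice not in ("a", "b"):
            raise ValueError("choice must be 'a' or 'b'")
        if not self.rt > 0:
            raise ValueError("rt must be positive")


@dataclass
class FitConfig:
    """Bounds, start grid and tolerances for per-subject estimation."""

    alpha_bounds: tuple[float, float] = (0.0, 1.0)
    lam_bounds: tuple[float, float] = (1e-6, 1.0)
    n_alpha_starts: int = 5
    n_lam_starts: int = 5
    polish_top_k: int = 3
    gtol: float = 1e-8
    maxiter: int = 200

    def start_grid(self) -> np.ndarray:
        """(n, 2) array of (alpha, lam) start points; lam log-spaced."""
        a = np.linspace(*self.alpha_bounds, self.n_alpha_starts)
        lo, hi = self.lam_bounds
        l = np.exp(np.linspace(np.log(lo), np.log(hi), self.n_lam_starts))
        aa, ll = np.meshgrid(a, l)
        return np.column_stack([aa.ravel(), ll.ravel()])


@dataclass
class FitResult:
    alpha_hat: float
    lam_hat: float
    neg_log_lik: float
    converged: bool
    n_trials: int
    condition: str | None = None
    lam_capped: bool = False


def utility(lottery: Lottery, alpha: float) -> float:
    """Quasi-maximin utility: alpha*min + (1-alpha)*EV, in JPY."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * lottery.minimum + (1.0 - alpha) * lottery.ev


def delta_u(pair: ChoicePair, alpha: float) -> float:
    """Absolute utility difference |U(a) - U(b)| at maximin weight alpha."""
    return abs(utility(pair.option_a, alpha) - utility(pair.option_b, alpha))


_EXP_CLIP = 500.0  # exponent clip; logistic saturates far earlier


def choice_probability(pair: ChoicePair, params: SubjectParams) -> float:
    """Softmax probability of choosing option_a."""
    du = utility(pair.option_a, params.alpha) - utility(pair.option_b, params.alpha)
    z = np.clip(params.lam * du, -_EXP_CLIP, _EXP_CLIP)
    return float(1.0 / (1.0 + np.exp(-z)))


def _trial_arrays(records: Sequence[ChoiceRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed (a - b) min/EV differences and choice signs (+1 for 'a')."""
    if len(records) == 0:
        raise ValueError("at least one choice record is required")
    mdiff = np.array([r.pair.option_a.minimum - r.pair.option_b.minimum for r in records])
    ediff = np.array([r.pair.option_a.ev - r.pair.option_b.ev for r in records])
    sign = np.array([1.0 if r.choice == "a" else -1.0 for r in records])
    return mdiff, ediff, sign


def _nll(theta: np.ndarray, mdiff: np.ndarray, ediff: np.ndarray, sign: np.ndarray) -> float:
    alpha, lam = theta
    u = alpha * mdiff + (1.0 - alpha) * ediff
    z = np.clip(sign * lam * u, -_EXP_CLIP, _EXP_CLIP)
    return float(np.sum(np.logaddexp(0.0, -z)))


def _nll_grad(theta: np.ndarray, mdiff: np.ndarray, ediff: np.ndarray, sign: np.ndarray) -> np.ndarray:
    alpha, lam = theta
    u = alpha * mdiff + (1.0 - alpha) * ediff
    z = np.clip(sign * lam * u, -_EXP_CLIP, _EXP_CLIP)
    w = -1.0 / (1.0 + np.exp(z))  # d/dz log(1+e^{-z})
    return np.array([
        np.sum(w * sign * lam * (mdiff - ediff)),
        np.sum(w * sign * u),
    ])


def negative_log_likelihood(records: Sequence[ChoiceRecord], params: SubjectParams) -> float:
    """Summed -ln P(observed choice) over trials, in nats."""
    mdiff, ediff, sign = _trial_arrays(records)
    return _nll(np.array([params.alpha, params.lam]), mdiff, ediff, sign)


def fit_subject(
    records: Sequence[ChoiceRecord],
    config: FitConfig | None = None,
    condition: str | None = None,
) -> FitResult:
    """Maximum-likelihood (alpha, lam) for one subject in one condition.

    The negative log-likelihood is evaluated at every point of the start grid
    and a bound-constrained quasi-Newton polish (L-BFGS-B with analytic
    gradient) is run from the best ``polish_top_k`` starts; the returned NLL
    is the minimum over all grid evaluations and polished solutions, so it is
    never above the NLL at any start point. The likelihood is convex in the
    reparametrization (lam*alpha, lam*(1-alpha)), which is why a small number
    of polished starts suffices.
    """
    if len(records) < 2:
        raise ValueError("need at least two trials to fit")
    config = config or FitConfig()
    mdiff, ediff, sign = _trial_arrays(records)
    if np.all((mdiff == 0) & (ediff == 0)):
        raise ValueError("all trials have identical options; parameters unidentifiable")

    starts = config.start_grid()
    # vectorized NLL over the start grid
    u = starts[:, 0:1] * mdiff + (1.0 - starts[:, 0:1]) * ediff  # (n_starts, n_trials)
    z = np.clip(sign * starts[:, 1:2] * u, -_EXP_CLIP, _EXP_CLIP)
    grid_nll = np.logaddexp(0.0, -z).sum(axis=1)

    order = np.argsort(grid_nll)
    best_theta = starts[order[0]]
    best_nll = float(grid_nll[order[0]])
    converged = False
    bounds = [config.alpha_bounds, config.lam_bounds]
    for idx in order[: config.polish_top_k]:
        res = minimize(
            _nll,
            starts[idx],
            args=(mdiff, ediff, sign),
            jac=_nll_grad,
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": config.gtol, "maxiter": config.maxiter},
        )
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_theta = res.x
            converged = bool(res.success)
        elif res.success and res.fun <= best_nll + 1e-12:
            converged = True

    lam_capped = bool(best_theta[1] >= config.lam_bounds[1] * (1 - 1e-9))
    return FitResult(
        alpha_hat=float(np.clip(best_theta[0], *config.alpha_bounds)),
        lam_hat=float(np.clip(best_theta[1], *config.lam_bounds)),
        neg_log_lik=best_nll,
        converged=converged and not lam_capped,
        n_trials=len(records),
        condition=condition,
        lam_capped=lam_capped,
    )


def grid_fit_oracle(
    records: Sequence[ChoiceRecord],
    alpha_grid: Iterable[float],
    lam_grid: Iterable[float],
    condition: str | None = None,
) -> FitResult:
    """Brute-force NLL minimization over an explicit (alpha, lam) grid.

    Serves as an independent check on :func:`fit_subject`: the optimizer's
    NLL must never exceed the grid minimum by more than a small tolerance.
    """
    alpha_grid = np.asarray(list(alpha_grid), dtype=float)
    lam_grid = np.asarray(list(lam_grid), dtype=float)
    if alpha_grid.size == 0 or lam_grid.size == 0:
        raise ValueError("grids must be non-empty")
    mdiff, ediff, sign = _trial_arrays(records)
    u = alpha_grid[:, None] * mdiff + (1.0 - alpha_grid[:, None]) * ediff
    # (n_alpha, n_lam, n_trials) via broadcasting
    z = np.clip(sign * lam_grid[None, :, None] * u[:, None, :], -_EXP_CLIP, _EXP_CLIP)
    nll = np.logaddexp(0.0, -z).sum(axis=2)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return FitResult(
        alpha_hat=float(alpha_grid[i]),
        lam_hat=float(lam_grid[j]),
        neg_log_lik=float(nll[i, j]),
        converged=True,
        n_trials=len(records),
        condition=condition,
    )
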