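"""Random-intercept logistic regression fit by Gauss-Hermite maximum
likelihood.

The marginal likelihood of each group (subject) integrates the Bernoulli
likelihood over a Gaussian random intercept; the integral is evaluated with
Gauss-Hermite quadrature (default 30 nodes), matching the approach of
lme4::glmer. Wald z statistics use the inverse of a finite-difference
Hessian at the optimum; the normal approximation is named in the output. If
the mixed fit fails, a plain fixed-effects logit is returned with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp
from scipy.stats import norm


@dataclass
class MixedLogitResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    method: str  # 'glmm-gh' or 'logit-fallback'
    penalized: bool = False

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.pvalues},
            index=self.names,
        )


def _aggregate(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Collapse Bernoulli rows to binomial cells per (group, design row)."""
    df = pd.DataFrame(X)
    df["_g"] = groups
    df["_y"] = y
    cols = [c for c in df.columns if c not in ("_y",)]
    agg = df.groupby(cols, sort=False)["_y"].agg(["sum", "count"]).reset_index()
    Xa = agg[[c for c in cols if c != "_g"]].to_numpy(dtype=float)
    return (
        agg["sum"].to_numpy(dtype=float),
        agg["count"].to_numpy(dtype=float),
        Xa,
        pd.factorize(agg["_g"])[0],
    )


def _fd_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_logit_mixed(
    y,
    X: pd.DataFrame,
    groups,
    n_quad: int = 30,
    ridge: float = 0.0,
    coef_bound: float = 15.0,
) -> MixedLogitResult:
    """ML fit of logit(P(y=1)) = X @ beta + u_group, u ~ N(0, sigma_u^2).

    ``X`` must include an intercept column. Near-separated data (any |beta|
    reaching ``coef_bound``) triggers a lightly ridge-penalized refit, which
    is flagged in the result.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    gv = np.asarray(groups)
    succ, tot, Xa, gidx = _aggregate(yv, Xv, gv)
    n_groups = int(gidx.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    def negll(theta: np.ndarray, pen: float) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = Xa @ beta  # (n_cells,)
        u = np.sqrt(2.0) * sigma * nodes  # (K,)
        z = eta[:, None] + u[None, :]
        ll_cells = succ[:, None] * log_expit(z) + (tot - succ)[:, None] * log_expit(-z)
        M = np.zeros((n_groups, n_quad))
        np.add.at(M, gidx, ll_cells)
        ll = logsumexp(M + log_w[None, :], axis=1).sum()
        return -ll + pen * float(beta @ beta)

    x0 = np.concatenate([np.zeros(len(names)), [np.log(0.5)]])
    res = minimize(lambda th: negll(th, ridge), x0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    penalized = False
    if not np.all(np.isfinite(res.x)) or np.any(np.abs(res.x[:-1]) >= coef_bound):
        warnings.warn("near-separation detected; using ridge-penalized mixed logit")
        res = minimize(lambda th: negll(th, max(ridge, 0.5)), x0, method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 500})
        penalized = True
    theta = res.x
    try:
        H = _fd_hessian(lambda th: negll(th, ridge if not penalized else 0.5), theta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov)[:-1])
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("mixed-logit Hessian not invertible; falling back to fixed-effects logit")
        import statsmodels.api as sm

        fit = sm.Logit(yv, Xv).fit(disp=0)
        return MixedLogitResult(
            names=names,
            coef=np.asarray(fit.params),
            se=np.asarray(fit.bse),
            sigma_u=0.0,
            loglik=float(fit.llf),
            converged=bool(fit.mle_retvals.get("converged", True)),
            method="logit-fallback",
        )
    return MixedLogitResult(
        names=names,
        coef=theta[:-1],
        se=se,
        sigma_u=float(np.exp(theta[-1])),
        loglik=-float(res.fun),
        converged=bool(res.success) or bool(np.linalg.norm(res.jac) < 1e-2),
        method="glmm-gh",
        penalized=penalized,
    )
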