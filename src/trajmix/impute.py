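"""Multiple imputation by chained equations and Rubin's-rules pooling.

Covariate missingness is handled by fully conditional specification:
continuous columns are imputed by Bayesian linear-regression draws (scaled
inverse-chi-square variance, normal coefficients, predictive noise, clipped
to the column's scale range) and binary columns by logistic draws from the
asymptotic coefficient distribution.  Polygenic-score columns are never
imputed — their analyses use complete cases.  Per-imputation analyses are
combined with Rubin's rules: total variance is the within-imputation mean
plus (1 + 1/m) times the between-imputation variance, with the standard
large-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .synthetic import BINARY_COLS, IMPUTABLE_COLS, PRS_COLS, SCALE_RANGES

_RIDGE = 1e-6


@dataclass
class ImputationSet:
    """m completed covariate tables (non-missing cells identical across all)."""

    tables: list[pd.DataFrame]
    method: str
    seed: int

    @property
    def m(self) -> int:
        return len(self.tables)


def _bayes_linear_draw(Xobs, yobs, Xmis, rng):
    n, p = Xobs.shape
    XtX = Xobs.T @ Xobs + _RIDGE * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xobs.T @ yobs)
    resid = yobs - Xobs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    C = sigma2 * (XtX_inv + XtX_inv.T) / 2
    beta = rng.multivariate_normal(beta_hat, C, method="cholesky")
    return Xmis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(Xmis))


def _logistic_draw(Xobs, yobs, Xmis, rng):
    # Newton-Raphson with a small ridge; draws from the asymptotic posterior
    n, p = Xobs.shape
    beta = np.zeros(p)
    for _ in range(50):
        mu = expit(Xobs @ beta)
        W = np.clip(mu * (1 - mu), 1e-8, None)
        H = Xobs.T @ (Xobs * W[:, None]) + _RIDGE * np.eye(p)
        g = Xobs.T @ (yobs - mu) - _RIDGE * beta
        step = np.linalg.solve(H, g)
        beta = np.clip(beta + step, -15, 15)
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = expit(Xobs @ beta)
    W = np.clip(mu * (1 - mu), 1e-8, None)
    H = Xobs.T @ (Xobs * W[:, None]) + _RIDGE * np.eye(p)
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2
    beta_draw = rng.multivariate_normal(beta, cov, method="cholesky")
    return (rng.random(len(Xmis)) < expit(Xmis @ beta_draw)).astype(float)


def impute_covariates(table: pd.DataFrame, m: int = 50, seed: int = 0,
                      n_burn: int = 10, min_observed: int = 10) -> ImputationSet:
    """Chained-equations imputation of the imputable covariate columns.

    Predictors are all other imputable columns (current completed values)
    plus mean age.  Sweep order follows the table's column order and is
    fixed; each of the m imputations runs on its own seeded substream, so
    the result is reproducible cell for cell.
    """
    cols = [c for c in IMPUTABLE_COLS if c in table.columns]
    with_missing = [c for c in cols if table[c].isna().any()]
    for c in with_missing:
        if table[c].notna().sum() < min_observed:
            raise ValueError(f"column {c!r} has fewer than {min_observed} "
                             "observed values; cannot impute")
    predictors = cols + (["mean_age"] if "mean_age" in table.columns else [])
    tables = []
    for j in range(m):
        rng = np.random.default_rng([seed, j])
        filled = table.copy()
        # start from observed-column means / binary modes
        for c in with_missing:
            obs = filled[c].dropna()
            start = (obs.mode().iloc[0] if c in BINARY_COLS else obs.mean())
            filled[c] = filled[c].fillna(start)
        miss_masks = {c: table[c].isna().to_numpy() for c in with_missing}
        for sweep in range(n_burn + 1):
            for c in with_missing:
                others = [p for p in predictors if p != c]
                X = np.column_stack(
                    [np.ones(len(filled))] + [filled[p].to_numpy() for p in others])
                X = np.where(np.isnan(X), 0.0, X)  # PRS-free predictors; mean_age complete
                y = filled[c].to_numpy()
                mis = miss_masks[c]
                if c in BINARY_COLS:
                    lo = float(table[c].dropna().min())
                    hi = float(table[c].dropna().max())
                    yb = (y[~mis] == hi).astype(float)
                    draw = _logistic_draw(X[~mis], yb, X[mis], rng)
                    filled.loc[mis, c] = np.where(draw == 1.0, hi, lo)
                else:
                    draw = _bayes_linear_draw(X[~mis], y[~mis], X[mis], rng)
                    if c in SCALE_RANGES:
                        draw = np.clip(draw, *SCALE_RANGES[c])
                    filled.loc[mis, c] = draw
        tables.append(filled)
    return ImputationSet(tables=tables, method="chained-equations", seed=seed)


@dataclass
class PooledResult:
    estimate: float
    se: float
    df: float
    p_value: float
    within_var: float
    between_var: float
    m: int
    flagged: bool = False


def rubin_pool(estimates, variances) -> PooledResult:
    """Combine per-imputation estimates with Rubin's rules.

    T = W + (1 + 1/m) B; df = (m - 1)(1 + W / ((1 + 1/m) B))^2; the two-sided
    p-value tests the pooled estimate against zero on a t reference.  With a
    single imputation the estimate is passed through with a normal-based p
    and flagged.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1 or len(est) < 1:
        raise ValueError("estimates and variances must be equal-length 1-d")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    m = len(est)
    qbar = float(est.mean())
    W = float(var.mean())
    if m == 1:
        se = float(np.sqrt(W))
        p = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else float(qbar == 0)
        return PooledResult(qbar, se, float("inf"), float(p), W, 0.0, 1,
                            flagged=True)
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B
    se = float(np.sqrt(T))
    if B < 1e-300:
        df = float("inf")
        p = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else float(qbar == 0)
    else:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else float(qbar == 0)
    return PooledResult(qbar, se, float(df), float(p), W, B, m)
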