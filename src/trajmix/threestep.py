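"""Three-step classify-analyze regression with classification-error correction.

Step 1 fits the latent class growth model without covariates; step 2 assigns
each participant to their modal class and quantifies the classification error
as the matrix D with D[s, k] = P(assigned s | true class k); step 3 regresses
the *assigned* class on covariates while holding D fixed, maximizing

    sum_i log sum_k P(C = k | x_i; beta) * D[W_i, k]

where P(C = k | x) is a multinomial logit and W_i the modal assignment.  With
an identity D this collapses to an ordinary multinomial logit on the modal
classes; with imperfect classification the D-mixture de-attenuates the
covariate effects.  Standard errors come from a cluster-robust sandwich over
family ids, the pragmatic fixed-effect reading of "multilevel" for sibling
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import softmax
from scipy.stats import norm

logger = logging.getLogger(__name__)

BETA_CAP = 15.0  # |coefficient| bound; hitting it flags separation


@dataclass
class Assignment:
    """Modal class assignment and its classification-error summary."""

    modal: np.ndarray          # (N,) modal class per participant
    D: np.ndarray              # (K, K): D[s, k] = P(assigned s | true k)
    avg_posterior: np.ndarray  # (K, K): mean posterior row per assigned class
    n_ties: int = 0


def modal_assign(posteriors: np.ndarray) -> Assignment:
    """Assign each row to its highest-posterior class and estimate D.

    Ties go to the lowest class index (argmax convention) and are logged.
    Columns of D sum to 1: each true class's probability mass is fully
    distributed over assigned classes.
    """
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    modal = post.argmax(axis=1)
    maxes = post.max(axis=1)
    n_ties = int(((post == maxes[:, None]).sum(axis=1) > 1).sum())
    if n_ties:
        logger.warning("%d tied posterior rows assigned to the lowest class index",
                       n_ties)
    col_mass = post.sum(axis=0)  # (K,)
    D = np.zeros((K, K))
    avg = np.zeros((K, K))
    for s in range(K):
        rows = post[modal == s]
        if len(rows):
            D[s] = rows.sum(axis=0)
            avg[s] = rows.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(col_mass > 0, D / col_mass, 0.0)
    return Assignment(modal=modal, D=D, avg_posterior=avg, n_ties=n_ties)


def grand_mean_center(column) -> np.ndarray:
    """Subtract the mean of the non-missing values; missing cells stay missing."""
    col = np.asarray(column, dtype=float)
    if np.all(np.isnan(col)):
        raise ValueError("cannot centre an all-missing column")
    return col - np.nanmean(col)


@dataclass
class MultinomialFit:
    """ML three-step multinomial logit with fixed classification error."""

    coef: np.ndarray           # (K, p); reference row all zero
    cov: np.ndarray            # ((K-1)p, (K-1)p), cluster-robust
    param_names: list[str]
    reference_class: int
    n_obs: int
    loglik: float
    converged: bool
    separation: bool
    modal_counts: np.ndarray   # (K,) assigned-class counts among used rows

    @property
    def n_classes(self) -> int:
        return self.coef.shape[0]

    def _flat_index(self, k: int, j: int) -> int:
        nonref = [c for c in range(self.n_classes) if c != self.reference_class]
        return nonref.index(k) * len(self.param_names) + j

    def contrast(self, a: int, b: int, coef_name: str = None):
        """log-odds difference beta_a - beta_b for one coefficient, with SE.

        Returns (estimate, se); either class may be the reference (zero
        coefficients, zero variance).  Classes with no assigned members make
        the contrast undefined -> (nan, nan).
        """
        j = (self.param_names.index(coef_name) if coef_name is not None else 1)
        if self.modal_counts[a] == 0 or self.modal_counts[b] == 0:
            return float("nan"), float("nan")
        diff = self.coef[a, j] - self.coef[b, j]
        c = np.zeros(self.cov.shape[0])
        if a != self.reference_class:
            c[self._flat_index(a, j)] = 1.0
        if b != self.reference_class:
            c[self._flat_index(b, j)] = -1.0
        se = float(np.sqrt(c @ self.cov @ c))
        return float(diff), se


def _neg_loglik_and_grad(beta_flat, X, dmat, nonref, K):
    n, p = X.shape
    beta = np.zeros((K, p))
    beta[nonref] = beta_flat.reshape(len(nonref), p)
    eta = X @ beta.T                     # (n, K)
    q = softmax(eta, axis=1)
    L = np.einsum("nk,nk->n", q, dmat)
    L = np.maximum(L, 1e-300)
    nll = -np.log(L).sum()
    # d log L_i / d eta_im = q_im (d_im - L_i) / L_i
    g_eta = q * (dmat - L[:, None]) / L[:, None]   # (n, K)
    grad = -(X.T @ g_eta[:, nonref]).T.reshape(-1)  # (len(nonref), p) flattened
    return nll, grad, g_eta


def corrected_multinomial_fit(modal: np.ndarray, D: np.ndarray,
                              predictors: pd.DataFrame,
                              family_ids: np.ndarray | None = None,
                              reference_class: int | None = None,
                              beta_cap: float = BETA_CAP) -> MultinomialFit:
    """Fit the error-corrected multinomial logit of class membership.

    ``predictors`` holds the regressors (covariate of interest first, then
    age and any extra adjusters); an intercept is prepended.  Rows with any
    missing predictor are dropped (complete-case within this fit; multiple
    imputation happens upstream).  ``family_ids`` define the clusters for
    the sandwich covariance; absent ids treat participants as independent.
    """
    K = D.shape[0]
    if D.shape != (K, K):
        raise ValueError("D must be square")
    if not np.allclose(D.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("columns of D must sum to 1")
    if reference_class is None:
        reference_class = K - 1
    pred = predictors.copy()
    keep = ~pred.isna().any(axis=1).to_numpy()
    pred = pred[keep]
    modal_used = np.asarray(modal)[keep]
    fam = (np.asarray(family_ids)[keep] if family_ids is not None
           else np.arange(keep.sum()))
    n = len(pred)
    X = np.column_stack([np.ones(n), pred.to_numpy(dtype=float)])
    names = ["intercept"] + list(pred.columns)
    p = X.shape[1]
    nonref = [c for c in range(K) if c != reference_class]
    dmat = D[modal_used]                 # (n, K): d_ik = D[W_i, k]

    res = optimize.minimize(
        lambda b: _neg_loglik_and_grad(b, X, dmat, nonref, K)[:2],
        x0=np.zeros(len(nonref) * p), jac=True, method="L-BFGS-B",
        bounds=[(-beta_cap, beta_cap)] * (len(nonref) * p),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    beta_flat = res.x
    separation = bool(np.any(np.abs(beta_flat) >= beta_cap - 1e-6))
    if separation:
        logger.warning("separation suspected: coefficient at the %.0f bound",
                       beta_cap)

    # observed information by central differences of the analytic gradient
    m = len(beta_flat)
    H = np.zeros((m, m))
    h = 1e-5
    for j in range(m):
        bp, bm = beta_flat.copy(), beta_flat.copy()
        bp[j] += h
        bm[j] -= h
        gp = _neg_loglik_and_grad(bp, X, dmat, nonref, K)[1]
        gm = _neg_loglik_and_grad(bm, X, dmat, nonref, K)[1]
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)

    _, _, g_eta = _neg_loglik_and_grad(beta_flat, X, dmat, nonref, K)
    scores = np.einsum("nk,nj->nkj", g_eta[:, nonref], X).reshape(n, m)
    fam_codes, fam_idx = np.unique(fam, return_inverse=True)
    G = np.zeros((len(fam_codes), m))
    np.add.at(G, fam_idx, scores)
    meat = G.T @ G
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
    cov = Hinv @ meat @ Hinv

    coef = np.zeros((K, p))
    coef[nonref] = beta_flat.reshape(len(nonref), p)
    counts = np.bincount(modal_used, minlength=K)
    return MultinomialFit(coef=coef, cov=cov, param_names=names,
                          reference_class=reference_class, n_obs=n,
                          loglik=-res.fun, converged=bool(res.success),
                          separation=separation, modal_counts=counts)


def contrast_table(fits: dict[str, MultinomialFit],
                   contrasts: list[tuple[int, int]],
                   class_names: list[str] | None = None,
                   coef_name: str | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Odds ratios with Wald CIs and p-values for the pre-specified contrasts.

    One row per (covariate, contrast a vs b): OR = exp(beta_a - beta_b) for
    the covariate coefficient, delta-method CI, two-sided normal p.  No
    multiple-testing adjustment is applied.
    """
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for cov_name, fit in fits.items():
        for a, b in contrasts:
            diff, se = fit.contrast(a, b, coef_name)
            if np.isnan(diff):
                rows.append({"covariate": cov_name, "class_a": a, "class_b": b,
                             "odds_ratio": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p_value": np.nan})
                continue
            pval = (2 * norm.sf(abs(diff) / se) if se > 0
                    else (0.0 if diff != 0 else 1.0))
            rows.append({
                "covariate": cov_name, "class_a": a, "class_b": b,
                "odds_ratio": float(np.exp(diff)),
                "ci_low": float(np.exp(diff - z * se)),
                "ci_high": float(np.exp(diff + z * se)),
                "p_value": float(pval),
            })
    out = pd.DataFrame(rows)
    if class_names is not None:
        out.insert(1, "contrast", [f"{class_names[a]} vs {class_names[b]}"
                                   for a, b in out[["class_a", "class_b"]].to_numpy()])
    return out


def simulate_misclassified_assignment(n: int, beta: float, error_rate: float,
                                      seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class calibration draw for the corrected estimator.

    True class 1 membership follows a logit with unit-variance Gaussian
    covariate x and per-unit log-odds ``beta`` (intercept 0); the modal
    assignment flips the true class with probability ``error_rate``.
    Returns (modal, D, x) with the exact generating D.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    p1 = 1.0 / (1.0 + np.exp(-(beta * x)))
    true = (rng.random(n) < p1).astype(int)
    flip = rng.random(n) < error_rate
    modal = np.where(flip, 1 - true, true)
    D = np.array([[1 - error_rate, error_rate],
                  [error_rate, 1 - error_rate]])
    return modal, D, x
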