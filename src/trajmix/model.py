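"""Parallel-process latent class growth model (LCGA) for two symptom domains.

The model: each participant belongs to one of K latent trajectory classes.
Within class k, the expected score for domain d (inattention or
hyperactivity-impulsivity) at age bin t is

    mu[d, t, k] = intercept[d, k] + lam[d, t] * slope[d, k]

with free loadings lam[d, t] (fixed to 0 at the first bin and 1 at the last
bin for identification), so the intercept is the expected first-bin score and
the slope is the total first-to-last change.  Within-class growth-factor
variance is zero (the LCGA restriction): all heterogeneity is between
classes.  Residuals are Gaussian, independent across bins and between domains
given class, with per-(domain, bin) variances.  Missing cells contribute
nothing (full-information maximum likelihood): a participant's likelihood is
the product of the densities of exactly their observed cells.

Estimation is EM with conditional M-steps (ECM): mixture weights, then
per-(domain, class) weighted least squares for growth factors given loadings,
then free loadings given growth factors, then residual variances.  Each sweep
is a generalized EM step, so the log-likelihood is non-decreasing; this is
asserted at every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

LOG_2PI = math.log(2.0 * math.pi)

DOMAINS = ("ia", "hi")
N_DOMAINS = 2


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices for the mixture growth model."""

    n_classes: int
    n_bins: int = 7
    loadings_shared_across_classes: bool = True
    residual_variances_shared_across_classes: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_bins < 3:
            raise ValueError("free loadings need at least 3 bins for identification")

    @property
    def n_params(self) -> int:
        K, T, D = self.n_classes, self.n_bins, N_DOMAINS
        p = (K - 1) + D * 2 * K
        p += D * (T - 2) * (1 if self.loadings_shared_across_classes else K)
        p += D * T * (1 if self.residual_variances_shared_across_classes else K)
        return p


@dataclass
class ModelParams:
    """Parameter set for a K-class parallel-process LCGA.

    Arrays are indexed by domain d (0 = inattention, 1 =
    hyperactivity-impulsivity), bin t and class k.  ``lam`` and ``sigma2``
    have shape (D, T) when shared across classes, else (D, K, T).
    """

    pi: np.ndarray         # (K,)
    intercept: np.ndarray  # (D, K)
    slope: np.ndarray      # (D, K)
    lam: np.ndarray        # (D, T) or (D, K, T)
    sigma2: np.ndarray     # (D, T) or (D, K, T)
    frozen_classes: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_classes(self) -> int:
        return self.pi.shape[0]

    @property
    def n_bins(self) -> int:
        return self.lam.shape[-1]

    @property
    def shared_loadings(self) -> bool:
        return self.lam.ndim == 2

    @property
    def shared_variances(self) -> bool:
        return self.sigma2.ndim == 2

    def lam_full(self) -> np.ndarray:
        """Loadings broadcast to shape (D, K, T)."""
        if self.shared_loadings:
            return np.broadcast_to(self.lam[:, None, :],
                                   (N_DOMAINS, self.n_classes, self.n_bins))
        return self.lam

    def sigma2_full(self) -> np.ndarray:
        if self.shared_variances:
            return np.broadcast_to(self.sigma2[:, None, :],
                                   (N_DOMAINS, self.n_classes, self.n_bins))
        return self.sigma2

    def means(self) -> np.ndarray:
        """Class mean curves, shape (D, K, T)."""
        return (self.intercept[:, :, None]
                + self.lam_full() * self.slope[:, :, None])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.pi)) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be finite and sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("mixture weights must be non-negative")
        for arr, name in ((self.intercept, "intercept"), (self.slope, "slope"),
                          (self.lam, "lam"), (self.sigma2, "sigma2")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")
        lam = self.lam_full()
        if not (np.allclose(lam[..., 0], 0.0) and np.allclose(lam[..., -1], 1.0)):
            raise ValueError("identification requires lam[.., 0] = 0 and lam[.., -1] = 1")

    def copy(self) -> "ModelParams":
        return ModelParams(self.pi.copy(), self.intercept.copy(),
                           self.slope.copy(), self.lam.copy(),
                           self.sigma2.copy(), self.frozen_classes)

    def permute_classes(self, order: np.ndarray) -> "ModelParams":
        """Relabel classes so new class j is old class order[j]."""
        lam = self.lam if self.shared_loadings else self.lam[:, order, :]
        sigma2 = self.sigma2 if self.shared_variances else self.sigma2[:, order, :]
        inv = {int(old): new for new, old in enumerate(order)}
        frozen = tuple(sorted(inv[k] for k in self.frozen_classes if k in inv))
        return ModelParams(self.pi[order], self.intercept[:, order],
                           self.slope[:, order], lam, sigma2, frozen)


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    n_params: int
    n_participants: int
    posteriors: np.ndarray  # (N, K)
    converged: bool
    n_iter: int
    best_start_id: int = 0
    ll_trace: np.ndarray | None = None
    start_logliks: list[float] | None = None
    final_fits: list["FitResult"] | None = None  # all converged finalists


def class_mean(params: ModelParams, d: int, t: int, k: int) -> float:
    """Expected score for domain d, bin t, class k."""
    lam = params.lam_full()[d, k, t]
    return float(params.intercept[d, k] + lam * params.slope[d, k])


def participant_loglik(obs_cells, params: ModelParams, k: int) -> float:
    """FIML log density of one participant's observed cells under class k.

    ``obs_cells`` is an iterable of (d, t, y) triples; missing cells are
    simply absent.  An empty set contributes 0 (a participant with no data
    is uninformative).
    """
    sigma2 = params.sigma2_full()
    total = 0.0
    for d, t, y in obs_cells:
        mu = class_mean(params, d, t, k)
        s2 = sigma2[d, k, t]
        total += -0.5 * (LOG_2PI + math.log(s2) + (y - mu) ** 2 / s2)
    return total


def _loglik_matrix(Y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-participant, per-class FIML log-likelihood, shape (N, K).

    Y has shape (D, N, T) with NaN marking missing cells.
    """
    D, N, T = Y.shape
    K = params.n_classes
    mu = params.means()            # (D, K, T)
    s2 = params.sigma2_full()      # (D, K, T)
    ll = np.zeros((N, K))
    # expand the Gaussian log density per cell and push the sums over bins
    # into (N, T) @ (T, K) matrix products
    for d in range(D):
        mask = ~np.isnan(Y[d])
        m = mask.astype(float)
        y = np.where(mask, Y[d], 0.0)
        inv = 1.0 / s2[d]                                      # (K, T)
        const = -0.5 * (LOG_2PI + np.log(s2[d]) + mu[d] ** 2 * inv)
        ll += m @ const.T + y @ (mu[d] * inv).T - 0.5 * (y * y) @ inv.T
    return ll


def mixture_loglik(Y: np.ndarray, params: ModelParams) -> float:
    """Total observed-data log-likelihood of the mixture, log-sum-exp stabilized."""
    params.validate()
    ll = _loglik_matrix(Y, params)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    return float(logsumexp(ll + logpi[None, :], axis=1).sum())


def e_step(Y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Posterior class-membership probabilities, shape (N, K); rows sum to 1."""
    ll = _loglik_matrix(Y, params)
    with np.errstate(divide="ignore"):
        logw = ll + np.log(params.pi)[None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    return np.exp(logw)


def m_step(Y: np.ndarray, post: np.ndarray, spec: ModelSpec,
           params: ModelParams) -> ModelParams:
    """One ECM sweep: weights, growth factors, free loadings, variances.

    Each block maximizes the expected complete-data log-likelihood given the
    others, so the sweep never decreases the observed-data log-likelihood.
    A (d, k) regression with posterior mass at fewer than two distinct bins is
    left at its current values and the class is flagged as frozen.
    """
    D, N, T = Y.shape
    K = spec.n_classes
    new = params.copy()
    new.pi = post.mean(axis=0)
    frozen: set[int] = set()

    masks = [~np.isnan(Y[d]) for d in range(D)]
    yfill = [np.where(masks[d], Y[d], 0.0) for d in range(D)]
    # posterior-weighted sufficient statistics per (d, k, t)
    WT = [post.T @ masks[d].astype(float) for d in range(D)]   # (K, T)
    WY = [post.T @ (yfill[d] * masks[d]) for d in range(D)]
    WY2 = [post.T @ (yfill[d] ** 2 * masks[d]) for d in range(D)]

    lam = new.lam_full().copy()      # (D, K, T)
    s2 = new.sigma2_full().copy()    # (D, K, T)

    # --- growth factors: per-(d, k) GLS of observed cells on (1, lam) ---
    for d in range(D):
        inv = 1.0 / s2[d]                              # (K, T)
        w = WT[d] * inv
        lkt = lam[d]
        S00 = w.sum(axis=1)
        S01 = (w * lkt).sum(axis=1)
        S11 = (w * lkt ** 2).sum(axis=1)
        Sy0 = (WY[d] * inv).sum(axis=1)
        Sy1 = (WY[d] * lkt * inv).sum(axis=1)
        det = S00 * S11 - S01 ** 2
        bins_hit = (WT[d] > 1e-10).sum(axis=1)
        good = (bins_hit >= 2) & (det > 1e-12 * np.maximum(S00 * S11, 1e-300))
        frozen.update(np.flatnonzero(~good).tolist())
        safe_det = np.where(good, det, 1.0)
        new.intercept[d] = np.where(good, (S11 * Sy0 - S01 * Sy1) / safe_det,
                                    new.intercept[d])
        new.slope[d] = np.where(good, (S00 * Sy1 - S01 * Sy0) / safe_det,
                                new.slope[d])

    # --- free loadings at interior bins given growth factors ---
    ic, sl = new.intercept, new.slope
    for d in range(D):
        inv = 1.0 / s2[d]
        num_kt = sl[d][:, None] * (WY[d] - ic[d][:, None] * WT[d]) * inv
        den_kt = sl[d][:, None] ** 2 * WT[d] * inv
        if spec.loadings_shared_across_classes:
            num = num_kt.sum(axis=0)
            den = den_kt.sum(axis=0)
            upd = den > 1e-10
            upd[[0, T - 1]] = False
            new.lam[d, upd] = num[upd] / den[upd]
        else:
            upd = den_kt > 1e-10
            upd[:, [0, T - 1]] = False
            if frozen:
                upd[sorted(frozen)] = False
            new.lam[d][upd] = num_kt[upd] / den_kt[upd]

    # --- residual variances given means ---
    lam = new.lam_full()
    mu = ic[:, :, None] + lam * sl[:, :, None]           # (D, K, T)
    for d in range(D):
        rss = WY2[d] - 2.0 * mu[d] * WY[d] + mu[d] ** 2 * WT[d]   # (K, T)
        if spec.residual_variances_shared_across_classes:
            tot_w = WT[d].sum(axis=0)
            tot_r = rss.sum(axis=0)
            ok = tot_w > 1e-10
            new.sigma2[d, ok] = np.maximum(tot_r[ok] / tot_w[ok], 1e-6)
        else:
            ok = WT[d] > 1e-10
            new.sigma2[d][ok] = np.maximum(rss[ok] / WT[d][ok], 1e-6)

    new.frozen_classes = tuple(sorted(frozen))
    return new


def em_fit(Y: np.ndarray, spec: ModelSpec, init: ModelParams,
           tol: float = 1e-6, max_iter: int = 500) -> FitResult:
    """Alternate E and ECM steps until the log-likelihood change falls below tol.

    Raises RuntimeError if the log-likelihood ever decreases by more than
    1e-8 — under a correct M-step that cannot happen, so a decrease signals
    an implementation defect rather than a data problem.
    """
    init.validate()
    params = init.copy()

    def _eval(p: ModelParams):
        # one likelihood-matrix pass serves both the LL and the posterior
        llm = _loglik_matrix(Y, p)
        with np.errstate(divide="ignore"):
            logw = llm + np.log(p.pi)[None, :]
        mx = logw.max(axis=1, keepdims=True)
        post = np.exp(logw - mx)
        norm = post.sum(axis=1, keepdims=True)
        lse = (mx + np.log(norm)).ravel()
        return float(lse.sum()), post / norm

    ll, post = _eval(params)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        params = m_step(Y, post, spec, params)
        ll_new, post = _eval(params)
        if ll_new < ll - 1e-8:
            raise RuntimeError(
                f"log-likelihood decreased ({ll:.10f} -> {ll_new:.10f}); "
                "M-step ascent violated")
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return FitResult(params=params, loglik=ll, n_params=spec.n_params,
                     n_participants=Y.shape[1], posteriors=post,
                     converged=converged, n_iter=n_iter,
                     ll_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# initialization and multi-start
# ---------------------------------------------------------------------------

def _profile_features(Y: np.ndarray) -> np.ndarray:
    """Per-participant summary features: observed mean and crude change per domain."""
    D, N, T = Y.shape
    feats = []
    for d in range(D):
        cnt = (~np.isnan(Y[d])).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, np.nansum(Y[d], axis=1) / np.maximum(cnt, 1),
                            np.nan)
        first = np.full(N, np.nan)
        last = np.full(N, np.nan)
        for t in range(T):
            col = Y[d][:, t]
            new_first = np.isnan(first) & ~np.isnan(col)
            first[new_first] = col[new_first]
        for t in range(T - 1, -1, -1):
            col = Y[d][:, t]
            new_last = np.isnan(last) & ~np.isnan(col)
            last[new_last] = col[new_last]
        feats.extend([mean, last - first])
    X = np.column_stack(feats)
    X = np.where(np.isnan(X), 0.0, X)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - X.mean(axis=0)) / sd


def initial_params(Y: np.ndarray, spec: ModelSpec,
                   rng: np.random.Generator, jitter: float = 0.3) -> ModelParams:
    """Random start: k-means partition of jittered participant profiles.

    Linear loadings and a pooled variance seed the first ECM sweep, which
    turns the hard partition into proper growth-factor estimates.
    """
    D, N, T = Y.shape
    K = spec.n_classes
    X = _profile_features(Y)
    Xj = X + rng.normal(0.0, jitter, size=X.shape)
    if K == 1:
        labels = np.zeros(N, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, max_iter=10,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        labels = km.fit_predict(Xj)
    hard = np.zeros((N, K))
    hard[np.arange(N), labels] = 1.0
    # seed parameter shapes
    lam0 = np.tile(np.linspace(0.0, 1.0, T), (D, 1))
    pooled_var = np.array([max(np.nanvar(Y[d]), 1.0) for d in range(D)])
    sigma2 = np.tile(pooled_var[:, None], (1, T))
    if not spec.loadings_shared_across_classes:
        lam0 = np.tile(lam0[:, None, :], (1, K, 1))
    if not spec.residual_variances_shared_across_classes:
        sigma2 = np.tile(sigma2[:, None, :], (1, K, 1))
    params = ModelParams(pi=np.full(K, 1.0 / K),
                         intercept=np.zeros((D, K)),
                         slope=np.zeros((D, K)),
                         lam=lam0, sigma2=sigma2)
    params = m_step(Y, hard, spec, params)
    # a jittered hard partition can leave a class empty; spread weights
    params.pi = np.maximum(params.pi, 1.0 / (4.0 * K))
    params.pi /= params.pi.sum()
    return params


def _is_degenerate(fit: FitResult) -> bool:
    return bool(np.any(fit.params.pi < 0.5 / fit.n_participants))


def split_class_inits(params: ModelParams, rng: np.random.Generator,
                      delta: float = 1.0) -> list[ModelParams]:
    """Warm starts for a (K+1)-class fit by splitting each class of a K-class
    solution in two (intercepts pushed +-delta with mild jitter, weight
    halved).  Seeding K+1 from the converged K solution keeps enumeration on
    the structured branch instead of relying on random starts alone."""
    K = params.n_classes
    if not (params.shared_loadings and params.shared_variances):
        raise ValueError("split warm starts support shared loadings/variances")
    inits = []
    for j in range(K):
        pi = np.concatenate([params.pi[:j], [params.pi[j] / 2] * 2,
                             params.pi[j + 1:]])
        ic = np.zeros((N_DOMAINS, K + 1))
        sl = np.zeros((N_DOMAINS, K + 1))
        for arr, src in ((ic, params.intercept), (sl, params.slope)):
            arr[:, :j] = src[:, :j]
            arr[:, j + 2:] = src[:, j + 1:]
        shift = delta * (1.0 + 0.25 * rng.normal(size=N_DOMAINS))
        ic[:, j] = params.intercept[:, j] + shift
        ic[:, j + 1] = params.intercept[:, j] - shift
        sl[:, j] = params.slope[:, j] + 0.25 * rng.normal(size=N_DOMAINS)
        sl[:, j + 1] = params.slope[:, j] - 0.25 * rng.normal(size=N_DOMAINS)
        inits.append(ModelParams(pi=pi, intercept=ic, slope=sl,
                                 lam=params.lam.copy(),
                                 sigma2=params.sigma2.copy()))
    return inits


def multi_start_fit(Y: np.ndarray, spec: ModelSpec,
                    n_initial: int = 100, n_final: int = 20,
                    seed: int | np.random.SeedSequence = 0,
                    stage1_iters: int = 20, tol: float = 1e-6,
                    max_iter: int = 500, max_retries: int = 50,
                    extra_inits: list[ModelParams] | None = None) -> FitResult:
    """Two-stage multi-start EM.

    ``n_initial`` random starts each run for a short fixed budget; the best
    ``n_final`` by log-likelihood are run to convergence and the best
    converged, non-degenerate fit is returned.  Starts whose smallest class
    drops below 1/(2N) are discarded and redrawn.  ``extra_inits`` join the
    first stage as additional (typically warm) starting values.  The sorted
    final-stage log-likelihoods are kept on the result so replication of the
    maximum can be inspected.
    """
    if n_final > n_initial:
        raise ValueError("n_final must be <= n_initial")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = iter(ss.spawn(n_initial + max_retries))
    stage1: list[tuple[float, int, ModelParams]] = []
    failures: list[str] = []
    for widx, winit in enumerate(extra_inits or []):
        try:
            wfit = em_fit(Y, spec, winit.copy(), tol=tol,
                          max_iter=stage1_iters)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures.append(f"warm start {widx}: {exc}")
            continue
        stage1.append((wfit.loglik, -(widx + 1), wfit.params))
    n_target = len(stage1) + n_initial
    sid = 0
    retries = 0
    while len(stage1) < n_target:
        try:
            rng = np.random.default_rng(next(children))
        except StopIteration:
            break
        try:
            init = initial_params(Y, spec, rng)
            fit = em_fit(Y, spec, init, tol=tol, max_iter=stage1_iters)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures.append(f"start {sid}: {exc}")
            retries += 1
            sid += 1
            continue
        if _is_degenerate(fit) and retries < max_retries:
            retries += 1
            sid += 1
            continue
        stage1.append((fit.loglik, sid, fit.params))
        sid += 1
    if not stage1:
        raise RuntimeError("all starts failed: " + "; ".join(failures[:5]))
    stage1.sort(key=lambda t: -t[0])
    best: FitResult | None = None
    final_lls: list[float] = []
    finalists: list[FitResult] = []
    for _, start_id, params in stage1[:n_final]:
        try:
            fit = em_fit(Y, spec, params, tol=tol, max_iter=max_iter)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures.append(f"final start {start_id}: {exc}")
            continue
        if _is_degenerate(fit):
            continue
        fit.best_start_id = start_id
        finalists.append(fit)
        final_lls.append(fit.loglik)
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        # fall back to the best stage-1 candidate run to convergence without
        # the degeneracy screen, so callers always get a diagnosable fit
        raise RuntimeError(
            "no non-degenerate converged fit among final starts: "
            + "; ".join(failures[:5]))
    best.start_logliks = sorted(final_lls, reverse=True)
    best.final_fits = sorted(finalists, key=lambda f: -f.loglik)
    return best


def severity_score(params: ModelParams) -> np.ndarray:
    """Per-class severity used for deterministic ordering.

    Severity is the inattention mean level averaged over bins:
    intercept + slope * mean(lam).
    """
    lam = params.lam_full()
    ia = params.intercept[0] + params.slope[0] * lam[0].mean(axis=-1)
    hi = params.intercept[1] + params.slope[1] * lam[1].mean(axis=-1)
    return np.column_stack([ia, hi])


def order_classes(fit: FitResult) -> FitResult:
    """Relabel classes by descending inattention severity.

    Ties break on hyperactivity-impulsivity severity, then original index,
    so the relabeling is deterministic and idempotent.  The likelihood is
    untouched: only labels move.
    """
    sev = severity_score(fit.params)
    K = fit.params.n_classes
    order = sorted(range(K), key=lambda k: (-sev[k, 0], -sev[k, 1], k))
    order = np.asarray(order)
    params = fit.params.permute_classes(order)
    return FitResult(params=params, loglik=fit.loglik, n_params=fit.n_params,
                     n_participants=fit.n_participants,
                     posteriors=fit.posteriors[:, order],
                     converged=fit.converged, n_iter=fit.n_iter,
                     best_start_id=fit.best_start_id,
                     ll_trace=fit.ll_trace, start_logliks=fit.start_logliks)
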