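import math

import numpy as np
import pytest

from trajmix.model import DOMAINS, ModelParams
from trajmix.synthetic import GeneratorConfig, apply_inclusion_filter, simulate_cohort

LOG_2PI = math.log(2.0 * math.pi)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (study-design defaults, fixed seed)."""
    config = GeneratorConfig(seed=20210403)
    dataset, covariates = simulate_cohort(config)
    return config, dataset, covariates


@pytest.fixture(scope="session")
def included_wide(default_cohort):
    _, dataset, _ = default_cohort
    included = apply_inclusion_filter(dataset)
    Y, pids = included.to_wide()
    return included, Y, pids


def make_toy_params(K=2, T=4, seed=0, shared=True):
    """Small valid parameter set with distinct class curves."""
    rng = np.random.default_rng(seed)
    lam_row = np.linspace(0.0, 1.0, T)
    lam = np.tile(lam_row, (2, 1))
    sigma2 = np.tile(rng.uniform(0.5, 2.0, size=(2, 1)), (1, T))
    if not shared:
        lam = np.tile(lam[:, None, :], (1, K, 1))
        sigma2 = np.tile(sigma2[:, None, :], (1, K, 1))
    pi = rng.dirichlet(np.full(K, 5.0))
    intercept = rng.uniform(2.0, 20.0, size=(2, K))
    slope = rng.uniform(-8.0, 8.0, size=(2, K))
    return ModelParams(pi=pi, intercept=intercept, slope=slope,
                       lam=lam, sigma2=sigma2)


def make_toy_Y(n=5, T=4, missing_frac=0.3, seed=1):
    """Random small data block with missing cells; every row keeps >=1 cell."""
    rng = np.random.default_rng(seed)
    Y = rng.uniform(0.0, 25.0, size=(2, n, T))
    mask = rng.random((2, n, T)) < missing_frac
    Y[mask] = np.nan
    for i in range(n):
        if np.all(np.isnan(Y[:, i, :])):
            Y[0, i, 0] = rng.uniform(0, 25)
    return Y


def brute_force_participant_loglik(Y, i, params, k):
    """Cell-by-cell Gaussian product, written independently of the package."""
    lam = params.lam_full()
    s2 = params.sigma2_full()
    total = 0.0
    for d in range(2):
        for t in range(Y.shape[2]):
            y = Y[d, i, t]
            if np.isnan(y):
                continue
            mu = params.intercept[d, k] + lam[d, k, t] * params.slope[d, k]
            total += -0.5 * (LOG_2PI + math.log(s2[d, k, t])
                             + (y - mu) ** 2 / s2[d, k, t])
    return total


def brute_force_mixture_loglik(Y, params):
    total = 0.0
    for i in range(Y.shape[1]):
        acc = 0.0
        for k in range(params.n_classes):
            acc += params.pi[k] * math.exp(
                brute_force_participant_loglik(Y, i, params, k))
        total += math.log(acc)
    return total


def brute_force_posteriors(Y, params):
    K = params.n_classes
    post = np.zeros((Y.shape[1], K))
    for i in range(Y.shape[1]):
        for k in range(K):
            post[i, k] = params.pi[k] * math.exp(
                brute_force_participant_loglik(Y, i, params, k))
        post[i] /= post[i].sum()
    return post
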