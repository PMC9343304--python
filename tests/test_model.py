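"""Growth mixture core: likelihood oracles, EM ascent, recovery, ordering."""

import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from conftest import (brute_force_mixture_loglik, brute_force_participant_loglik,
                      brute_force_posteriors, make_toy_params, make_toy_Y)
from trajmix.model import (FitResult, ModelParams, ModelSpec, class_mean,
                           e_step, em_fit, initial_params, m_step,
                           mixture_loglik, multi_start_fit, order_classes,
                           participant_loglik)


class TestClassMean:
    def test_identification_endpoints(self):
        params = make_toy_params(K=3, T=5)
        for d in range(2):
            for k in range(3):
                assert class_mean(params, d, 0, k) == pytest.approx(
                    params.intercept[d, k])
                assert class_mean(params, d, 4, k) == pytest.approx(
                    params.intercept[d, k] + params.slope[d, k])

    def test_default_generator_curve(self):
        # severe combined decreasing inattention: 20 at entry, 9 at the end
        from trajmix.synthetic import default_true_params
        params = default_true_params()
        assert class_mean(params, 0, 6, 2) == pytest.approx(9.0)
        assert class_mean(params, 0, 0, 2) == pytest.approx(20.0)


class TestParticipantLoglik:
    def test_standard_normal_mode(self):
        params = make_toy_params(K=1, T=4, seed=3)
        params.sigma2[:] = 1.0
        y_at_mean = class_mean(params, 0, 1, 0)
        ll = participant_loglik([(0, 1, y_at_mean)], params, 0)
        assert ll == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)))

    def test_empty_cells_contribute_zero(self):
        params = make_toy_params()
        assert participant_loglik([], params, 0) == 0.0

    def test_missing_domain_marginalizes(self):
        """Dropping all HI cells leaves exactly the IA-only product density."""
        params = make_toy_params(K=2, T=4, seed=4)
        cells = [(0, 0, 5.0), (0, 2, 7.0), (1, 1, 3.0), (1, 3, 2.0)]
        ia_only = [c for c in cells if c[0] == 0]
        hi_terms = participant_loglik([c for c in cells if c[0] == 1], params, 1)
        assert participant_loglik(cells, params, 1) == pytest.approx(
            participant_loglik(ia_only, params, 1) + hi_terms)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        params = make_toy_params(K=3, T=5, seed=seed)
        Y = make_toy_Y(n=6, T=5, seed=seed + 10)
        for i in range(6):
            cells = [(d, t, Y[d, i, t]) for d in range(2) for t in range(5)
                     if not np.isnan(Y[d, i, t])]
            for k in range(3):
                assert participant_loglik(cells, params, k) == pytest.approx(
                    brute_force_participant_loglik(Y, i, params, k), abs=1e-10)


class TestMixtureLoglik:
    def test_single_class_degenerate(self):
        params = make_toy_params(K=1, T=4, seed=5)
        Y = make_toy_Y(n=5, T=4, seed=6)
        direct = sum(
            brute_force_participant_loglik(Y, i, params, 0) for i in range(5))
        assert mixture_loglik(Y, params) == pytest.approx(direct, abs=1e-10)

    def test_duplication_additivity(self):
        params = make_toy_params(K=2, T=4, seed=7)
        Y = make_toy_Y(n=4, T=4, seed=8)
        Y2 = np.concatenate([Y, Y], axis=1)
        assert mixture_loglik(Y2, params) == pytest.approx(
            2 * mixture_loglik(Y, params), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        params = make_toy_params(K=2, T=4, seed=seed)
        Y = make_toy_Y(n=5, T=4, seed=seed + 20)
        assert mixture_loglik(Y, params) == pytest.approx(
            brute_force_mixture_loglik(Y, params), abs=1e-10)

    def test_rejects_nonfinite_params(self):
        params = make_toy_params()
        params.slope[0, 0] = np.inf
        with pytest.raises(ValueError):
            mixture_loglik(make_toy_Y(), params)

    def test_fiml_equals_analytic_marginalization(self):
        """Deleting a cell changes the loglik by exactly that cell's term."""
        params = make_toy_params(K=1, T=4, seed=9)
        Y = make_toy_Y(n=3, T=4, missing_frac=0.0, seed=9)
        Ydel = Y.copy()
        Ydel[0, 1, 2] = np.nan
        cell_term = brute_force_participant_loglik(Y, 1, params, 0) - \
            brute_force_participant_loglik(Ydel, 1, params, 0)
        assert mixture_loglik(Y, params) - mixture_loglik(Ydel, params) == \
            pytest.approx(cell_term, abs=1e-10)


class TestEStep:
    def test_identical_classes_uniform(self):
        params = make_toy_params(K=3, T=4, seed=10)
        for k in (1, 2):
            params.intercept[:, k] = params.intercept[:, 0]
            params.slope[:, k] = params.slope[:, 0]
        params.pi = np.full(3, 1 / 3)
        post = e_step(make_toy_Y(n=4, T=4, seed=11), params)
        assert np.allclose(post, 1 / 3)

    def test_degenerate_weights(self):
        params = make_toy_params(K=2, T=4, seed=12)
        params.pi = np.array([1.0, 0.0])
        post = e_step(make_toy_Y(n=4, T=4, seed=13), params)
        assert np.allclose(post[:, 0], 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bayes_rule(self, seed):
        params = make_toy_params(K=3, T=5, seed=seed)
        Y = make_toy_Y(n=6, T=5, seed=seed + 30)
        post = e_step(Y, params)
        assert np.allclose(post, brute_force_posteriors(Y, params), atol=1e-10)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_noiseless_fixed_point(self):
        """Data exactly on the mean curves reproduce the generating params."""
        true = make_toy_params(K=2, T=5, seed=14)
        true.lam[:, 1:-1] = np.array([[0.3, 0.5, 0.8], [0.2, 0.6, 0.9]])
        n_per = 8
        Y = np.empty((2, 2 * n_per, 5))
        for k in range(2):
            mu = true.means()[:, k, :]
            Y[:, k * n_per:(k + 1) * n_per, :] = mu[:, None, :]
        post = np.zeros((2 * n_per, 2))
        post[:n_per, 0] = 1.0
        post[n_per:, 1] = 1.0
        spec = ModelSpec(n_classes=2, n_bins=5)
        upd = m_step(Y, post, spec, true.copy())
        assert np.allclose(upd.intercept, true.intercept, atol=1e-8)
        assert np.allclose(upd.slope, true.slope, atol=1e-8)
        assert np.allclose(upd.lam, true.lam, atol=1e-8)

    def test_concentrated_posterior_is_ols(self):
        """All mass in one class reduces the growth update to plain OLS."""
        rng = np.random.default_rng(15)
        T = 5
        lam_row = np.linspace(0, 1, T)
        Y = np.empty((2, 20, T))
        for d in range(2):
            Y[d] = 4.0 + 6.0 * lam_row + rng.normal(0, 1, size=(20, T))
        params = make_toy_params(K=2, T=T, seed=16)
        params.lam[:] = lam_row
        params.sigma2[:] = 1.0
        post = np.column_stack([np.ones(20), np.zeros(20)])
        upd = m_step(Y, post, ModelSpec(n_classes=2, n_bins=T), params)
        X = np.column_stack([np.ones(20 * T), np.tile(lam_row, 20)])
        for d in range(2):
            beta, *_ = np.linalg.lstsq(X, Y[d].ravel(), rcond=None)
            assert upd.intercept[d, 0] == pytest.approx(beta[0], abs=1e-8)
            assert upd.slope[d, 0] == pytest.approx(beta[1], abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_sweep_never_decreases_loglik(self, seed):
        Y = make_toy_Y(n=30, T=5, missing_frac=0.2, seed=seed)
        params = make_toy_params(K=3, T=5, seed=seed + 40)
        spec = ModelSpec(n_classes=3, n_bins=5)
        before = mixture_loglik(Y, params)
        post = e_step(Y, params)
        after = mixture_loglik(Y, m_step(Y, post, spec, params))
        assert after >= before - 1e-8


class TestEmFit:
    def test_single_class_closed_form(self):
        """K=1 fit matches the closed-form alternating WLS solution."""
        rng = np.random.default_rng(17)
        T = 5
        lam_true = np.array([0.0, 0.2, 0.55, 0.8, 1.0])
        Y = np.empty((2, 200, T))
        for d in range(2):
            Y[d] = (10.0 - 2 * d) + (6.0 + d) * lam_true + \
                rng.normal(0, 0.5, size=(200, T))
        spec = ModelSpec(n_classes=1, n_bins=T)
        init = initial_params(Y, spec, np.random.default_rng(0))
        fit = em_fit(Y, spec, init, tol=1e-10, max_iter=2000)
        # with K=1, complete data and free loadings the mean structure is
        # saturated: the MLE interpolates the per-bin sample means, so the
        # closed-form solution is intercept = first-bin mean, slope = total
        # change, sigma2 = per-bin mean squared deviation
        for d in range(2):
            ybar = Y[d].mean(axis=0)
            lam_hat = fit.params.lam[d]
            assert np.allclose(fit.params.intercept[d, 0]
                               + lam_hat * fit.params.slope[d, 0],
                               ybar, atol=1e-6)
            assert fit.params.intercept[d, 0] == pytest.approx(ybar[0], abs=1e-6)
            assert fit.params.slope[d, 0] == pytest.approx(
                ybar[-1] - ybar[0], abs=1e-6)
            assert np.allclose(fit.params.sigma2[d],
                               ((Y[d] - ybar) ** 2).mean(axis=0), atol=1e-5)

    def test_class_specific_loadings_and_variances(self):
        """The non-shared parameterization keeps EM ascent and beats the
        shared fit in likelihood (it nests it)."""
        rng = np.random.default_rng(60)
        T = 5
        Y = np.empty((2, 80, T))
        lam_a = np.array([0.0, 0.1, 0.3, 0.6, 1.0])
        lam_b = np.array([0.0, 0.5, 0.8, 0.9, 1.0])
        for d in range(2):
            Y[d, :40] = 15.0 - 8.0 * lam_a + rng.normal(0, 1.0, (40, T))
            Y[d, 40:] = 5.0 + 9.0 * lam_b + rng.normal(0, 2.0, (40, T))
        shared_spec = ModelSpec(n_classes=2, n_bins=T)
        free_spec = ModelSpec(n_classes=2, n_bins=T,
                              loadings_shared_across_classes=False,
                              residual_variances_shared_across_classes=False)
        shared = multi_start_fit(Y, shared_spec, n_initial=6, n_final=2,
                                 seed=61)
        free = multi_start_fit(Y, free_spec, n_initial=6, n_final=2, seed=61)
        assert free.params.lam.shape == (2, 2, T)
        assert free.params.sigma2.shape == (2, 2, T)
        assert np.all(np.diff(free.ll_trace) >= -1e-8)
        assert free.loglik >= shared.loglik - 1e-6
        assert free_spec.n_params > shared_spec.n_params

    def test_ll_trace_monotone(self):
        Y = make_toy_Y(n=40, T=5, seed=18)
        spec = ModelSpec(n_classes=2, n_bins=5)
        init = initial_params(Y, spec, np.random.default_rng(19))
        fit = em_fit(Y, spec, init)
        assert np.all(np.diff(fit.ll_trace) >= -1e-8)

    def test_infinite_tol_single_iteration(self):
        Y = make_toy_Y(n=20, T=4, seed=20)
        spec = ModelSpec(n_classes=2, n_bins=4)
        init = initial_params(Y, spec, np.random.default_rng(21))
        fit = em_fit(Y, spec, init, tol=np.inf)
        assert fit.n_iter == 1
        assert fit.loglik >= fit.ll_trace[0]

    def test_init_at_truth_stays_close(self, included_wide, default_cohort):
        """Starting at the generating parameters, EM stays in the same basin.

        The residual drift reflects sampling noise in the ~50-member classes
        plus the mild clipping bias near the scale floor, both bounded well
        below the between-class separation (>= 5 score units).
        """
        config, _, _ = default_cohort
        _, Y, _ = included_wide
        spec = ModelSpec(n_classes=7)
        fit = em_fit(Y, spec, config.true_params.copy(), tol=1e-4)
        assert np.max(np.abs(fit.params.intercept
                             - config.true_params.intercept)) < 2.0
        assert np.max(np.abs(fit.params.slope
                             - config.true_params.slope)) < 2.0
        assert np.max(np.abs(fit.params.pi - config.true_params.pi)) < 0.02


class TestMultiStart:
    def test_single_start_equals_em_fit(self):
        Y = make_toy_Y(n=40, T=5, seed=22)
        spec = ModelSpec(n_classes=2, n_bins=5)
        fit = multi_start_fit(Y, spec, n_initial=1, n_final=1, seed=23,
                              stage1_iters=20)
        # same stream layout: the first spawned child seeds the first start
        child = np.random.SeedSequence(23).spawn(1)[0]
        init = initial_params(Y, spec, np.random.default_rng(child))
        direct = em_fit(Y, spec, em_fit(Y, spec, init, max_iter=20).params)
        assert fit.loglik == pytest.approx(direct.loglik, abs=1e-6)

    def test_best_ll_nondecreasing_in_starts(self):
        Y = make_toy_Y(n=60, T=5, seed=24)
        spec = ModelSpec(n_classes=3, n_bins=5)
        ll_small = multi_start_fit(Y, spec, n_initial=3, n_final=2, seed=25).loglik
        ll_large = multi_start_fit(Y, spec, n_initial=12, n_final=4, seed=25).loglik
        assert ll_large >= ll_small - 1e-6

    def test_rejects_bad_budgets(self):
        with pytest.raises(ValueError):
            multi_start_fit(make_toy_Y(), ModelSpec(n_classes=2, n_bins=4),
                            n_initial=2, n_final=5)

    def test_no_degenerate_class_returned(self, included_wide):
        _, Y, _ = included_wide
        fit = multi_start_fit(Y, ModelSpec(n_classes=4), n_initial=10,
                              n_final=3, seed=26)
        assert fit.params.pi.min() >= 0.5 / Y.shape[1]


class TestOrderClasses:
    def _fit_from_params(self, params, Y):
        post = e_step(Y, params)
        return FitResult(params=params, loglik=mixture_loglik(Y, params),
                         n_params=0, n_participants=Y.shape[1],
                         posteriors=post, converged=True, n_iter=1)

    def test_idempotent_and_permutation_invariant(self):
        params = make_toy_params(K=4, T=5, seed=27)
        Y = make_toy_Y(n=10, T=5, seed=28)
        fit = self._fit_from_params(params, Y)
        once = order_classes(fit)
        twice = order_classes(once)
        assert np.allclose(once.params.intercept, twice.params.intercept)
        assert np.allclose(once.posteriors, twice.posteriors)
        perm = np.array([2, 0, 3, 1])
        shuffled = self._fit_from_params(params.permute_classes(perm), Y)
        back = order_classes(shuffled)
        assert np.allclose(back.params.intercept, once.params.intercept)
        assert np.allclose(back.params.pi, once.params.pi)

    def test_loglik_invariant_under_relabeling(self):
        params = make_toy_params(K=3, T=4, seed=29)
        Y = make_toy_Y(n=8, T=4, seed=30)
        fit = self._fit_from_params(params, Y)
        ordered = order_classes(fit)
        assert mixture_loglik(Y, ordered.params) == pytest.approx(
            fit.loglik, abs=1e-9)

    def test_descending_severity(self):
        params = make_toy_params(K=4, T=5, seed=31)
        Y = make_toy_Y(n=10, T=5, seed=32)
        ordered = order_classes(self._fit_from_params(params, Y))
        lam_mean = ordered.params.lam[0].mean()
        sev = ordered.params.intercept[0] + ordered.params.slope[0] * lam_mean
        assert np.all(np.diff(sev) <= 1e-9)


class TestParameterRecovery:
    def test_growth_factor_recovery(self, included_wide, default_cohort):
        """Aligned 7-class estimates sit close to the generating values."""
        config, _, _ = default_cohort
        _, Y, _ = included_wide
        fit = multi_start_fit(Y, ModelSpec(n_classes=7), n_initial=60,
                              n_final=12, seed=99)
        true = config.true_params
        est = np.column_stack([fit.params.intercept[0], fit.params.slope[0],
                               fit.params.intercept[1], fit.params.slope[1]])
        gen = np.column_stack([true.intercept[0], true.slope[0],
                               true.intercept[1], true.slope[1]])
        cost = ((est[:, None, :] - gen[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        aligned = est[rows][np.argsort(cols)]
        # growth-factor and loading bands cover sampling noise in the ~50
        # member classes plus the truncation shift (up to ~1.3 score units
        # at the scale floor) that the free loadings partially absorb
        assert np.max(np.abs(aligned - gen[np.sort(cols)])) < 2.5
        assert np.max(np.abs(np.sort(fit.params.lam, axis=1)
                             - np.sort(true.lam, axis=1))) < 0.12
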