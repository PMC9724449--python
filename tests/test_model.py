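"""Core model maths: reconstruction, modulation, likelihood, gradients, gauge."""

import numpy as np
import pytest

from modsig import (
    ModulatoryFit,
    ZeroRateError,
    additive_reconstruction,
    gauge_fix,
    grad_activities,
    grad_modulatory_activity,
    grad_modulatory_profile,
    log_likelihood,
    modulation_factors,
)


def random_instance(rng, n_s=4, n_c=7, n_sig=3):
    """A random feasible model instance on an arbitrary channel count."""
    M = rng.dirichlet(np.ones(n_c), size=n_sig)
    A = rng.uniform(0.5, 30.0, size=(n_s, n_sig))
    r = rng.uniform(-1.0, 1.0, size=n_c)
    r /= max(1.0, np.abs(r).max())
    c = rng.uniform(0.0, 0.9, size=n_s)
    fit = ModulatoryFit(r, c)
    rates = (1.0 + np.outer(c, r)) * (A @ M)
    X = rng.poisson(rates).astype(float)
    return X, A, M, fit


class TestAdditiveReconstruction:
    def test_uniform_signature(self):
        M = np.full((1, 96), 1 / 96)
        A = np.array([[100.0]])
        np.testing.assert_allclose(additive_reconstruction(A, M), np.full((1, 96), 100 / 96))

    def test_zero_activity_gives_zeros(self):
        M = np.full((2, 96), 1 / 96)
        assert np.all(additive_reconstruction(np.zeros((3, 2)), M) == 0)

    def test_disjoint_support_hand_check(self):
        # 4-channel toy: mu1 on channels 0-1, mu2 on channels 2-3
        M = np.array([[0.25, 0.75, 0.0, 0.0], [0.0, 0.0, 0.6, 0.4]])
        A = np.array([[10.0, 20.0]])
        np.testing.assert_allclose(
            additive_reconstruction(A, M), [[2.5, 7.5, 12.0, 8.0]]
        )

    def test_negative_activities_rejected(self):
        with pytest.raises(ValueError):
            additive_reconstruction(np.array([[-1.0]]), np.full((1, 4), 0.25))


class TestModulationFactors:
    def test_inactive_sample_gives_ones(self):
        fit = ModulatoryFit(np.linspace(-1, 1, 5), np.zeros(3))
        assert np.all(modulation_factors(fit) == 1.0)

    @pytest.mark.parametrize("r,c,expected", [(1.0, 2.5, 3.5), (-0.5, 2.0, 0.0)])
    def test_closed_form(self, r, c, expected):
        fit = ModulatoryFit(np.array([r]), np.array([c]))
        assert modulation_factors(fit)[0, 0] == pytest.approx(expected)

    def test_infeasible_rejected(self):
        fit = ModulatoryFit(np.array([-0.9]), np.array([2.0]))
        with pytest.raises(ValueError, match="infeasible"):
            modulation_factors(fit)


class TestLogLikelihood:
    def test_all_zero_counts_closed_form(self, rng):
        rates = rng.uniform(0.1, 5.0, size=(3, 8))
        ll = log_likelihood(np.zeros((3, 8)), rates, None)
        assert ll == pytest.approx(-rates.sum())

    def test_single_cell_closed_form(self):
        ll = log_likelihood(np.array([[3.0]]), np.array([[3.0]]), None)
        assert ll == pytest.approx(-3 + 3 * np.log(3))

    def test_inactive_modulation_equals_additive(self, rng):
        X, A, M, _ = random_instance(rng)
        Xhat = A @ M
        fit0 = ModulatoryFit(rng.uniform(-1, 1, X.shape[1]), np.zeros(X.shape[0]))
        assert log_likelihood(X, Xhat, fit0) == pytest.approx(log_likelihood(X, Xhat, None))

    def test_zero_rate_with_positive_count_is_error(self):
        with pytest.raises(ZeroRateError):
            log_likelihood(np.array([[2.0]]), np.array([[0.0]]), None)


class TestGradients:
    def test_stationary_at_truth_noiseless(self, rng):
        _, A, M, fit = random_instance(rng)
        X = (1.0 + np.outer(fit.c, fit.r)) * (A @ M)  # continuous "counts"
        g_a = grad_activities(X, M, A, fit)
        g_r = grad_modulatory_profile(X, A @ M, fit)
        g_c = grad_modulatory_activity(X, A @ M, fit)
        assert np.abs(g_a).max() < 1e-8 * X.sum()
        assert np.abs(g_r).max() < 1e-8 * X.sum()
        assert np.abs(g_c).max() < 1e-8 * X.sum()

    def test_gradients_match_central_finite_differences(self):
        # the module's oracle: 100 random feasible instances
        rng = np.random.default_rng(2024)
        h = 1e-6
        for _ in range(100):
            X, A, M, fit = random_instance(rng)
            Xhat = A @ M

            def ll_a(Aflat):
                return log_likelihood(X, Aflat.reshape(A.shape) @ M, fit)

            def ll_r(r):
                return log_likelihood(X, Xhat, ModulatoryFit(r, fit.c))

            def ll_c(c):
                return log_likelihood(X, Xhat, ModulatoryFit(fit.r, c))

            for grad, func, x0 in [
                (grad_activities(X, M, A, fit).ravel(), ll_a, A.ravel()),
                (grad_modulatory_profile(X, Xhat, fit), ll_r, fit.r),
                (grad_modulatory_activity(X, Xhat, fit), ll_c, fit.c),
            ]:
                num = np.empty_like(x0)
                for i in range(x0.size):
                    e = np.zeros_like(x0)
                    e[i] = h * max(1.0, abs(x0[i]))
                    num[i] = (func(x0 + e) - func(x0 - e)) / (2 * e[i])
                rel = np.abs(grad - num) / (1.0 + np.abs(grad))
                assert rel.max() < 1e-6

    def test_profile_gradient_vanishes_without_activity(self, rng):
        X, A, M, fit = random_instance(rng)
        fit0 = ModulatoryFit(fit.r, np.zeros_like(fit.c))
        assert np.all(grad_modulatory_profile(X, A @ M, fit0) == 0.0)

    def test_activity_gradient_vanishes_without_profile(self, rng):
        X, A, M, fit = random_instance(rng)
        fit0 = ModulatoryFit(np.zeros_like(fit.r), fit.c)
        assert np.all(grad_modulatory_activity(X, A @ M, fit0) == 0.0)

    def test_single_cell_closed_forms(self):
        X = np.array([[4.0]])
        Xhat = np.array([[2.0]])
        fit = ModulatoryFit(np.array([0.5]), np.array([0.8]))
        p = 1 + 0.8 * 0.5
        assert grad_modulatory_profile(X, Xhat, fit)[0] == pytest.approx(
            4 * 0.8 / p - 0.8 * 2
        )
        assert grad_modulatory_activity(X, Xhat, fit)[0] == pytest.approx(
            4 * 0.5 / p - 0.5 * 2
        )

    def test_boundary_term_finite_where_count_zero(self):
        # p = 0 at a zero-count cell: only the -r*Xhat term survives
        X = np.array([[0.0]])
        Xhat = np.array([[3.0]])
        fit = ModulatoryFit(np.array([-0.5]), np.array([2.0]))
        g = grad_modulatory_activity(X, Xhat, fit)
        assert np.isfinite(g[0])
        assert g[0] == pytest.approx(1.5)  # -r*Xhat

    def test_uniform_signature_reduction(self):
        # c = 0, single uniform signature: gradient = sum(X)/a - 1
        n_c = 96
        M = np.full((1, n_c), 1 / n_c)
        a = 50.0
        rng = np.random.default_rng(3)
        X = rng.poisson(a / n_c, size=(1, n_c)).astype(float)
        fit = ModulatoryFit(np.zeros(n_c), np.zeros(1))
        g = grad_activities(X, M, np.array([[a]]), fit)
        assert g[0, 0] == pytest.approx(X.sum() / a - 1.0)


class TestGauge:
    def test_stated_rule(self):
        fit = gauge_fix(ModulatoryFit(np.array([0.5, -0.25]), np.array([2.0])))
        np.testing.assert_allclose(fit.r, [1.0, -0.5])
        np.testing.assert_allclose(fit.c, [1.0])

    def test_idempotent(self, rng):
        fit = gauge_fix(ModulatoryFit(rng.uniform(-1, 1, 8), rng.uniform(0, 1, 3)))
        again = gauge_fix(fit)
        np.testing.assert_array_equal(fit.r, again.r)
        np.testing.assert_array_equal(fit.c, again.c)

    def test_zero_profile_deactivates(self):
        fit = gauge_fix(ModulatoryFit(np.zeros(5), np.array([0.7, 0.2])))
        assert np.all(fit.c == 0.0)

    def test_likelihood_invariant_under_gauge(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            X, A, M, fit = random_instance(rng)
            raw = ModulatoryFit(fit.r * rng.uniform(0.2, 0.9), fit.c)
            Xhat = A @ M
            assert log_likelihood(X, Xhat, gauge_fix(raw)) == pytest.approx(
                log_likelihood(X, Xhat, raw), abs=1e-10 * max(1.0, X.sum())
            )

    def test_gauge_invariance_of_likelihood_under_rescaling(self, rng):
        # r -> r/alpha, c -> alpha*c leaves every modulation factor unchanged
        X, A, M, fit = random_instance(rng)
        Xhat = A @ M
        base = log_likelihood(X, Xhat, fit)
        for alpha in (0.25, 2.0, 17.0):
            scaled = ModulatoryFit(fit.r / alpha, fit.c * alpha)
            assert log_likelihood(X, Xhat, scaled) == pytest.approx(base, abs=1e-10 * max(1.0, abs(base)))

    def test_modulation_factors_preserved_by_gauge(self, rng):
        _, _, _, fit = random_instance(rng)
        raw = ModulatoryFit(fit.r * 0.3, fit.c)
        np.testing.assert_allclose(
            modulation_factors(gauge_fix(raw)), modulation_factors(raw), atol=1e-12
        )


class TestConcavityInC:
    def test_no_spurious_optima_in_1d_activity_scan(self, rng):
        # the likelihood is concave in c for fixed a, r: a fine scan of a
        # single-sample problem must be unimodal
        X, A, M, fit = random_instance(rng, n_s=1)
        Xhat = A @ M
        grid = np.linspace(0.0, 0.95 / max(1e-9, -fit.r.min()), 300)
        vals = np.array(
            [log_likelihood(X, Xhat, ModulatoryFit(fit.r, np.array([c]))) for c in grid]
        )
        d = np.diff(vals)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
        assert sign_changes <= 1


class TestGaugeProperties:
    """Randomized gauge properties via hypothesis."""

    def test_gauge_canonicalises_any_feasible_fit(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            r=hnp.arrays(np.float64, 12, elements=st.floats(-3, 3, allow_nan=False)),
            c=hnp.arrays(np.float64, 4, elements=st.floats(0, 2, allow_nan=False)),
        )
        def check(r, c):
            fit = gauge_fix(ModulatoryFit(r, c))
            if np.any(r != 0):
                assert np.abs(fit.r).max() == pytest.approx(1.0)
                # products c*r, and hence all modulation factors, unchanged
                np.testing.assert_allclose(
                    np.outer(fit.c, fit.r), np.outer(c, r), atol=1e-9
                )
            else:
                assert np.all(fit.c == 0.0)

        check()
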