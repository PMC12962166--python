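"""Circular-statistics unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbcoord import circstats as cs

angles = st.floats(min_value=-50.0, max_value=50.0, allow_nan=False)


@given(angles)
@settings(deadline=None)
def test_wrap_angle_range_and_periodicity(a):
    w = cs.wrap_angle(a)
    assert -np.pi <= w < np.pi
    assert cs.wrap_angle(a + 2 * np.pi) == pytest.approx(w, abs=1e-9)


@given(st.lists(angles, min_size=1, max_size=50))
@settings(deadline=None)
def test_circ_mean_invariant_to_2pi_shifts(sample):
    a = np.array(sample)
    m1 = cs.circ_mean(a)
    m2 = cs.circ_mean(a + 2 * np.pi)
    assert abs(cs.circ_dist(m1, m2)) < 1e-9


class TestVmKde:
    def test_single_phase_peak_and_symmetry(self):
        d = cs.vm_kde([0.0])
        peak = d.grid[np.argmax(d.density)]
        assert abs(peak) < 2 * np.pi / 200 + 1e-12
        # symmetric about 0: density at theta equals density at -theta
        interp = np.interp(-d.grid[1:], d.grid, d.density, period=2 * np.pi)
        np.testing.assert_allclose(d.density[1:], interp, rtol=1e-6)

    def test_uniform_sample_approaches_uniform_density(self, rng):
        d = cs.vm_kde(rng.uniform(-np.pi, np.pi, 40_000))
        np.testing.assert_allclose(d.density, 1 / (2 * np.pi), rtol=0.05)

    def test_integral_is_one(self, rng):
        for n in (1, 5, 500):
            d = cs.vm_kde(rng.vonmises(1.0, 3.0, n))
            assert d.integral() == pytest.approx(1.0, abs=1e-6)

    def test_reflection_equivariance(self, rng):
        """Mirroring the data mirrors the density (stimulation-side correction)."""
        ph = rng.vonmises(0.7, 4.0, 300)
        d = cs.vm_kde(ph)
        dm = cs.vm_kde(-ph)
        mirrored = np.interp(-d.grid, dm.grid, dm.density, period=2 * np.pi)
        np.testing.assert_allclose(d.density, mirrored, rtol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.vm_kde([])


class TestVmMixture:
    def test_single_component_recovery(self, rng):
        mu = 0.54 * np.pi
        sel, _ = cs.fit_vm_mixture(rng.vonmises(mu, 8.0, 2000), seed=0)
        assert sel.n_components == 1
        assert abs(cs.circ_dist(sel.means[0], mu)) < 0.05 * np.pi
        assert sel.kappas[0] == pytest.approx(8.0, rel=0.25)

    def test_two_component_recovery(self, rng):
        ph = np.concatenate([rng.vonmises(0.0, 12.0, 1000), rng.vonmises(np.pi, 12.0, 1000)])
        sel, _ = cs.fit_vm_mixture(ph, seed=0)
        assert sel.n_components == 2
        np.testing.assert_allclose(np.sort(sel.weights), [0.5, 0.5], atol=0.05)

    def test_loglik_nondecreasing_within_em(self, rng):
        sel, fits = cs.fit_vm_mixture(rng.vonmises(0.0, 2.0, 400), n_components=(2,), seed=3)
        trace = fits[2].loglik_trace
        assert np.all(np.diff(trace) > -1e-6)

    def test_degenerate_identical_phases_capped(self):
        sel, _ = cs.fit_vm_mixture(np.full(100, 0.3), n_components=(1,), seed=0)
        assert sel.n_components == 1
        assert sel.kappa_capped
        assert sel.kappas[0] >= 499.0

    def test_weights_sum_to_one_and_wrapped_means(self, rng):
        sel, fits = cs.fit_vm_mixture(rng.vonmises(1.0, 3.0, 500), seed=1)
        for f in fits.values():
            assert np.sum(f.weights) == pytest.approx(1.0, abs=1e-9)
            assert np.all(f.means >= -np.pi) and np.all(f.means < np.pi)

    def test_deterministic_given_seed(self, rng):
        ph = rng.vonmises(0.0, 4.0, 300)
        a, _ = cs.fit_vm_mixture(ph, seed=9)
        b, _ = cs.fit_vm_mixture(ph, seed=9)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestUnimodality:
    def _fit(self, means, kappas, weights):
        k = len(means)
        return cs.VMMixtureFit(
            n_components=k,
            means=np.array(means, float),
            kappas=np.array(kappas, float),
            weights=np.array(weights, float),
            log_likelihood=0.0,
            bic=0.0,
            n=100,
            converged=True,
        )

    def test_single_component_is_criterion_1(self):
        assert cs.unimodality_check(self._fit([0.0], [5.0], [1.0])) == (True, 1)

    def test_dominant_component_is_criterion_2(self):
        fit = self._fit([0.0, 2.0], [5.0, 5.0], [0.85, 0.15])
        assert cs.unimodality_check(fit) == (True, 2)

    def test_two_close_components_criterion_3_and_far_fails(self):
        near = self._fit([0.0, 0.1 * np.pi, 2.0], [5, 5, 5], [0.5, 0.45, 0.05])
        assert cs.unimodality_check(near) == (True, 3)
        far = self._fit([0.0, 0.5 * np.pi, 2.0], [5, 5, 5], [0.5, 0.45, 0.05])
        assert cs.unimodality_check(far) == (False, None)


class TestCircLinearRegression:
    def test_intercept_only_equals_circular_mean(self, rng):
        ph = rng.vonmises(1.2, 4.0, 400)
        fit = cs.circ_linear_regression(ph, np.empty((400, 0)), n_boot=0)
        assert abs(cs.circ_dist(fit.mu0, cs.circ_mean(ph))) < 1e-6

    def test_recovers_generating_slope(self, rng):
        x = rng.uniform(-20, 20, 2000)
        beta = -0.03
        ph = rng.vonmises(0.8 * np.pi + 2 * np.arctan(beta * x), 8.0)
        fit = cs.circ_linear_regression(ph, x[:, None], ["angle"], n_boot=100, seed=0)
        # point estimate close to truth; interval coverage is checked over
        # many replicate cohorts in the acceptance suite
        assert fit.beta[0] == pytest.approx(beta, abs=0.005)
        lo, hi = fit.intervals["angle"]
        assert lo < hi
        assert fit.significant["angle"]

    def test_bias_shrinks_with_sample_size(self, rng):
        beta = -0.03
        errs = []
        for n in (200, 2000):
            x = rng.uniform(-20, 20, n)
            ph = rng.vonmises(0.5 + 2 * np.arctan(beta * x), 8.0)
            fit = cs.circ_linear_regression(ph, x[:, None], ["x"], n_boot=0)
            errs.append(abs(fit.beta[0] - beta))
        assert errs[1] < errs[0]

    def test_vif_screen_drops_aliased_column(self, rng):
        x = rng.normal(size=500)
        X = np.column_stack([x, x * 1.0000001 + rng.normal(0, 1e-8, 500)])
        ph = rng.vonmises(2 * np.arctan(0.5 * x), 5.0)
        fit = cs.circ_linear_regression(ph, X, ["a", "b"], n_boot=0)
        assert len(fit.dropped_covariates) == 1

    def test_group_offsets_sum_to_zero(self, rng):
        g = np.repeat([0, 1, 2], 200)
        ph = cs.wrap_angle(rng.vonmises(0.5, 6.0, 600) + np.array([-0.3, 0.0, 0.3])[g])
        fit = cs.circ_linear_regression(ph, np.empty((600, 0)), groups=g, n_boot=0)
        assert fit.group_offsets.sum() == pytest.approx(0.0, abs=1e-6)
        spread = fit.group_offsets[2] - fit.group_offsets[0]
        assert spread == pytest.approx(0.6, abs=0.1)


class TestCircCircCorrelation:
    def test_identity_and_antisymmetry(self, rng):
        a = rng.vonmises(0.0, 2.0, 500)
        assert cs.circ_circ_correlation(a, a) == pytest.approx(1.0)
        assert cs.circ_circ_correlation(a, -a) == pytest.approx(-1.0)

    def test_independent_uniform_near_zero(self, rng):
        u = rng.uniform(-np.pi, np.pi, 10_000)
        v = rng.uniform(-np.pi, np.pi, 10_000)
        assert abs(cs.circ_circ_correlation(u, v)) < 0.05

    def test_invariant_to_2pi_shift(self, rng):
        a = rng.vonmises(0.5, 3.0, 200)
        b = rng.vonmises(-0.5, 3.0, 200)
        r1 = cs.circ_circ_correlation(a, b)
        r2 = cs.circ_circ_correlation(a + 2 * np.pi, b - 2 * np.pi)
        assert r1 == pytest.approx(r2, abs=1e-9)
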