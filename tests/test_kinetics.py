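"""Smoluchowski kinetics, stability ratio, size-aware model and fits."""

import math

import numpy as np
import pytest

import nanoagg as na
from nanoagg.constants import KB_J


@pytest.fixture(scope="module")
def suspension():
    return na.SuspensionParams(radius=1.50, phi=0.008)


@pytest.fixture(scope="module")
def W_full(suspension):
    return na.stability_ratio(suspension).W


class TestHydrodynamicB:
    def test_hand_arithmetic_at_h_equals_r(self):
        assert na.hydrodynamic_B(1.0, 1.0) == pytest.approx(2.1)

    def test_tends_to_one_far_away(self):
        assert na.hydrodynamic_B(1e8, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_decreasing_and_above_one(self):
        h = np.logspace(-4, 4, 500)
        b = na.hydrodynamic_B(h, 1.0)
        assert np.all(np.diff(b) < 0)
        assert np.all(b > 1.0)

    def test_contact_divergence_raises(self):
        with pytest.raises(ValueError):
            na.hydrodynamic_B(0.0, 1.0)


class TestStabilityRatio:
    def test_ideal_diffusion_closed_form(self, suspension):
        """No hydrodynamics, no potential: the kernel integrates to
        exactly 1."""
        res = na.stability_ratio(suspension, with_hydro=False, potential=None)
        assert abs(res.W - 1.0) < 1e-9

    def test_attraction_accelerates_aggregation(self, suspension):
        res = na.stability_ratio(suspension, with_hydro=False)
        assert res.W < 1.0

    def test_matches_fixed_grid_trapezoid_oracle(self, suspension, W_full):
        """Independent quadrature: trapezoid over a dense log-spaced h
        grid of the raw integrand 2R B(h) (h+2R)^-2 exp(W_A/kBT)."""
        R = suspension.radius
        kbt = na.KB_KJ_MOL_K * suspension.T
        h = np.logspace(np.log10(1e-8 * R), np.log10(1e6 * R), 100_000)
        wa = na.dlvo_attraction(h + 2 * R, R, suspension.hamaker)
        x = h / R
        b = (6 * x**2 + 13 * x + 2) / (6 * x**2 + 4 * x)
        integrand = 2 * R * b / (h + 2 * R) ** 2 * np.exp(np.maximum(wa / kbt, -700))
        oracle = np.trapezoid(integrand, h)
        assert W_full == pytest.approx(oracle, rel=1e-3)

    def test_scale_invariance_in_radius(self):
        # the Hamaker attraction depends only on d/R, so W is radius-free
        w1 = na.stability_ratio(na.SuspensionParams(radius=0.78, phi=0.01)).W
        w2 = na.stability_ratio(na.SuspensionParams(radius=2.0, phi=0.01)).W
        assert w1 == pytest.approx(w2, rel=1e-8)


class TestAggregationTime:
    def test_si_arithmetic_oracle(self):
        p = na.SuspensionParams(radius=0.78, phi=0.008, mu=6.913e-4, T=310.0)
        expected_s = (
            math.pi * 6.913e-4 * (0.78e-9) ** 3 * 1.0 / (KB_J * 310.0 * 0.008)
        )
        assert na.aggregation_time(p, 1.0) == pytest.approx(expected_s * 1e6, rel=1e-12)

    def test_proportionalities(self, suspension):
        tp = na.aggregation_time(suspension, 1.0)
        double_phi = na.SuspensionParams(radius=1.50, phi=0.016)
        assert na.aggregation_time(double_phi, 1.0) == pytest.approx(tp / 2)
        assert na.aggregation_time(suspension, 10.0) == pytest.approx(10 * tp)

    def test_rejects_nonpositive_w(self, suspension):
        with pytest.raises(ValueError):
            na.aggregation_time(suspension, 0.0)


class TestSmoluchowskiN:
    def test_values_and_linearity(self):
        assert na.smoluchowski_N(0.0, 2.0) == 1.0
        assert na.smoluchowski_N(2.0, 2.0) == 2.0
        t = np.array([1.0, 2.0])
        n = na.smoluchowski_N(t, 4.0)
        assert n[1] - n[0] == pytest.approx(1.0 / 4.0)


class TestModifiedTrace:
    def test_nesting_recovers_linear_law(self, suspension, W_full):
        """n2 = 0, n3 = 1 reproduces 1 + t/tp (the recursion is exactly
        linear, so only roundoff remains); halving dt does not grow the
        residual."""
        tp = na.aggregation_time(suspension, W_full)
        for dt in (tp / 500, tp / 1000):
            tr = na.modified_trace(0.0, 1.0, suspension, W_full, dt, 30.0)
            expected = na.smoluchowski_N(tr.times, tp)
            assert np.max(np.abs(tr.mean_size - expected)) < 1e-8 * expected.max()

    def test_slowdown_bounded_by_linear_model(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        tr = na.modified_trace(0.3, 1.0, suspension, W_full, tp / 1000, 10.0)
        assert np.all(tr.mean_size <= na.smoluchowski_N(tr.times, tp) + 1e-12)
        assert np.all(np.diff(tr.mean_size) >= 0)

    def test_richardson_halving_dt(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        coarse = na.modified_trace(0.141, 0.181, suspension, W_full, tp / 250, 10.0)
        fine = na.modified_trace(0.141, 0.181, suspension, W_full, tp / 500, 10.0)
        finest = na.modified_trace(0.141, 0.181, suspension, W_full, tp / 1000, 10.0)
        err_coarse = np.max(np.abs(coarse.mean_size - finest.mean_size))
        err_fine = np.max(np.abs(fine.mean_size - finest.mean_size))
        assert err_fine < err_coarse

    def test_large_dt_warns(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        with pytest.warns(UserWarning, match="dt too large"):
            na.modified_trace(0.0, 0.001, suspension, W_full, 2 * tp, 10.0,
                              n_frames=10)


class TestFitN1:
    def test_exact_recovery_of_rescaled_tp(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        t = np.linspace(0, 20, 100)
        for truth in (1.0, 2.0):
            trace = na.KineticsTrace(
                times=t,
                mean_size=na.smoluchowski_N(t, truth * tp),
                n_clusters=500.0 / na.smoluchowski_N(t, truth * tp),
                n_total=500.0,
            )
            assert na.fit_n1(trace, suspension, W_full) == pytest.approx(truth, rel=1e-9)

    def test_noisy_recovery(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        rng = np.random.default_rng(13)
        t = np.linspace(0, 20, 200)
        clean = na.smoluchowski_N(t, 1.5 * tp)
        estimates = []
        for _ in range(30):
            noisy = np.maximum(clean * (1 + 0.05 * rng.standard_normal(t.size)), 1.0)
            trace = na.KineticsTrace(
                times=t, mean_size=noisy, n_clusters=500.0 / noisy, n_total=500.0
            )
            estimates.append(na.fit_n1(trace, suspension, W_full))
        se = np.std(estimates) / math.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(1.5, abs=3 * se + 0.01)

    def test_flat_trace_raises(self, suspension, W_full):
        t = np.linspace(0, 10, 50)
        trace = na.KineticsTrace(
            times=t, mean_size=np.ones_like(t), n_clusters=np.full_like(t, 500.0),
            n_total=500.0,
        )
        with pytest.raises(ValueError, match="flat"):
            na.fit_n1(trace, suspension, W_full)


class TestFitN2N3:
    @pytest.mark.parametrize("key", sorted(na.ANATASE_KINETIC_COEFFS))
    def test_noiseless_round_trip_all_reference_pairs(self, key):
        """Every reference (n2, n3) pair is recovered to 1e-3 from a
        noiseless model-generated 30 us trace."""
        radius, phi = key
        n2, n3 = na.ANATASE_KINETIC_COEFFS[key]
        params = na.SuspensionParams(radius=radius, phi=phi)
        W = na.stability_ratio(params).W
        tp = na.aggregation_time(params, W)
        # trace length scaled with tp so every configuration shows the
        # same relative growth; recovery is exact for any consistent dt
        dt = tp / 200
        trace = na.synthetic_kinetics_trace(
            n2, max(n3, 1e-3), params, W, dt, t_end=min(30.0, 2000 * tp)
        )
        fit = na.fit_n2_n3(trace, params, W, dt)
        assert fit.n2 == pytest.approx(n2, abs=1e-3)
        assert fit.n3 == pytest.approx(max(n3, 1e-3), abs=1e-3)
        assert fit.rmse < 1e-6

    def test_noisy_monte_carlo_recovery(self, suspension, W_full):
        """With 5% multiplicative noise the mean of 50 replicate fits
        recovers both coefficients within 3 standard errors."""
        tp = na.aggregation_time(suspension, W_full)
        dt = tp / 200
        n2_true, n3_true = 0.141, 0.181
        est = np.empty((50, 2))
        for rep in range(50):
            trace = na.synthetic_kinetics_trace(
                n2_true, n3_true, suspension, W_full, dt, 30.0,
                noise_sigma=0.05, seed=1000 + rep,
            )
            fit = na.fit_n2_n3(trace, suspension, W_full, dt)
            est[rep] = fit.n2, fit.n3
        se = est.std(axis=0) / math.sqrt(len(est))
        assert abs(est[:, 0].mean() - n2_true) < 3 * se[0]
        assert abs(est[:, 1].mean() - n3_true) < 3 * se[1]

    def test_boundary_nested_model_recovered(self, suspension, W_full):
        tp = na.aggregation_time(suspension, W_full)
        trace = na.synthetic_kinetics_trace(
            0.0, 1.0, suspension, W_full, tp / 1000, t_end=10.0
        )
        fit = na.fit_n2_n3(trace, suspension, W_full, tp / 1000)
        assert fit.n2 == pytest.approx(0.0, abs=1e-6)
        assert fit.n3 == pytest.approx(1.0, abs=1e-6)

    def test_filtered_frames_do_not_affect_fit(self, suspension, W_full):
        """Frames with <= 5 aggregates may be corrupted arbitrarily
        without changing the fit: the frame filter removes them."""
        tp = na.aggregation_time(suspension, W_full)
        dt = tp / 1000
        base = na.synthetic_kinetics_trace(
            0.141, 0.181, suspension, W_full, dt, t_end=30.0
        )
        # push late frames below the frame filter (consistently with the
        # conservation invariant) to create a filtered tail
        mean = base.mean_size.copy()
        mean[-20:] = base.n_total / 4.0  # 4 clusters in the box
        trace = na.KineticsTrace(
            times=base.times, n_clusters=base.n_total / mean, mean_size=mean,
            n_total=base.n_total,
        )
        mask = trace.n_clusters <= 5
        assert mask.any()
        fit_ref = na.fit_n2_n3(trace, suspension, W_full, dt)
        # corrupting mean size upward keeps those frames below the filter
        corrupt = trace.mean_size.copy()
        corrupt[mask] *= 17.3
        corrupted = na.KineticsTrace(
            times=trace.times, n_clusters=trace.n_total / corrupt,
            mean_size=corrupt, n_total=trace.n_total,
        )
        fit_corr = na.fit_n2_n3(corrupted, suspension, W_full, dt)
        assert fit_corr.n2 == pytest.approx(fit_ref.n2, abs=1e-9)
        assert fit_corr.n3 == pytest.approx(fit_ref.n3, abs=1e-9)

    def test_too_few_filtered_frames_raises(self, suspension, W_full):
        t = np.linspace(0, 5, 10)
        mean = 1 + t
        trace = na.KineticsTrace(
            times=t, mean_size=mean, n_clusters=4.0 / mean, n_total=4.0
        )  # at most 4 clusters: every frame fails the > 5 filter
        with pytest.raises(ValueError, match="aggregates"):
            na.fit_n2_n3(trace, suspension, W_full, 0.01)


class TestRmse:
    def _trace(self, t, n, total=100.0):
        return na.KineticsTrace(
            times=t, mean_size=n, n_clusters=total / n, n_total=total
        )

    def test_identical_traces_zero(self):
        t = np.linspace(0, 5, 20)
        tr = self._trace(t, 1 + t)
        assert na.rmse(tr, tr) == 0.0

    def test_constant_offset(self):
        t = np.linspace(0, 5, 20)
        a = self._trace(t, 1 + t)
        b = self._trace(t, 1 + t + 0.7)
        assert na.rmse(b, a) == pytest.approx(0.7)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 5, 30)
        x = 1 + t + rng.uniform(0, 1, t.size)
        y = 1 + t + rng.uniform(0, 1, t.size)
        expected = np.sqrt(np.mean((x - y) ** 2))
        assert na.rmse(self._trace(t, x), self._trace(t, y)) == pytest.approx(expected)

    def test_disjoint_time_ranges_raise(self):
        a = self._trace(np.linspace(0, 1, 5), np.ones(5) * 2)
        b = self._trace(np.linspace(2, 3, 5), np.ones(5) * 2)
        with pytest.raises(ValueError, match="overlap"):
            na.rmse(a, b)
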