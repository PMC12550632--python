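"""Stretched-exponential fits, the Poisson universal curve, off-rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from cfmavidity import (
    CurveOrigin,
    DetachmentCurve,
    TrialPoint,
    af_from_lambda,
    fit_stretched_exponential,
    fit_universal_curve,
    lambda_from_af,
    off_rate_vs_force,
    stretched_exponential,
)
from cfmavidity.force import ForceTrace


def make_curve(t, f, norm=1000.0):
    return DetachmentCurve(t, f, norm, CurveOrigin.CENTRIFUGE_START)


class TestPoissonAdhesion:
    def test_reference_values(self):
        assert af_from_lambda(0.0) == 0.0
        assert af_from_lambda(np.log(2.0)) == pytest.approx(0.5, rel=1e-12)
        assert af_from_lambda(1.0) == pytest.approx(0.63212, abs=1e-5)

    def test_matches_poisson_tail_sum(self):
        # AF is the Poisson mass at one or more bonds; cross-check against
        # the summed pmf truncated at 1e-12
        for lam in (0.3, 1.0, 2.5):
            tail = sum(poisson.pmf(x, lam) for x in range(1, 60))
            assert af_from_lambda(lam) == pytest.approx(tail, abs=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            af_from_lambda(-0.1)

    def test_lambda_from_af_examples(self):
        assert lambda_from_af(0.0) == 0.0
        assert lambda_from_af(0.632) == pytest.approx(1.0, abs=2e-3)
        with pytest.raises(ValueError):
            lambda_from_af(1.2)

    @settings(derandomize=True, max_examples=50)
    @given(af=st.floats(min_value=0.0, max_value=0.999))
    def test_round_trip_inverse(self, af):
        assert af_from_lambda(lambda_from_af(af)) == pytest.approx(af, abs=1e-12)

    def test_monotone_and_concave(self):
        lam = np.linspace(0.0, 8.0, 200)
        af = af_from_lambda(lam)
        assert np.all(np.diff(af) > 0)
        assert np.all(np.diff(af, 2) < 0)
        assert af_from_lambda(40.0) == pytest.approx(1.0, abs=1e-12)


class TestStretchedExponential:
    def test_boundary_values(self):
        t = np.array([0.0, 1e9])
        for g, tau, beta in [(0.3, 10.0, 0.7), (1.0, 50.0, 2.0)]:
            f = stretched_exponential(t, g, tau, beta)
            assert f[0] == 1.0
            assert f[1] == pytest.approx(1.0 - g, abs=1e-9)

    def test_noiseless_recovery(self):
        t = np.arange(0.0, 240.0, 0.25)
        g, tau, beta = 0.9, 40.0, 1.5
        fit = fit_stretched_exponential(make_curve(t, stretched_exponential(t, g, tau, beta)))
        assert fit.g == pytest.approx(g, rel=1e-6)
        assert fit.tau_s == pytest.approx(tau, rel=1e-6)
        assert fit.beta == pytest.approx(beta, rel=1e-6)
        assert fit.converged

    def test_reduces_to_simple_exponential(self):
        t = np.arange(0.0, 200.0, 0.5)
        tau0 = 30.0
        fit = fit_stretched_exponential(make_curve(t, np.exp(-t / tau0)))
        assert fit.tau_s == pytest.approx(tau0, rel=1e-4)
        assert fit.beta == pytest.approx(1.0, rel=1e-4)
        assert fit.g == pytest.approx(1.0, rel=1e-4)

    def test_flat_curve_flagged(self):
        t = np.arange(0.0, 100.0, 0.5)
        fit = fit_stretched_exponential(make_curve(t, np.ones_like(t)))
        assert "g_at_lower_bound" in fit.flags

    def test_too_few_points_rejected(self):
        t = np.arange(0.0, 2.0, 0.5)
        with pytest.raises(ValueError, match="10 points"):
            fit_stretched_exponential(make_curve(t, np.exp(-t)))

    def test_lifetime_grows_with_valency(self, cell, ramp_protocol):
        from cfmavidity import BondModel, build_detachment_curve, simulate_trial

        taus = []
        for lam in (1.0, 2.0):
            trial = simulate_trial(
                BondModel(lam=lam), ramp_protocol, cell=cell, n_cells=1000, seed=11
            )
            curve = build_detachment_curve(trial.count_trace, t_origin_s=120.0)
            taus.append(fit_stretched_exponential(curve).tau_s)
        assert taus[1] > taus[0]


class TestUniversalCurve:
    def points_on_curve(self, k, x0, lams, n_cells=800):
        return [
            TrialPoint(float(af_from_lambda(l)), k * l + x0, n_cells=n_cells)
            for l in lams
        ]

    def test_exact_recovery_on_noiseless_points(self):
        pts = self.points_on_curve(15.4, 3.5, np.linspace(0.2, 5.0, 12))
        fit = fit_universal_curve(pts)
        assert fit.k == pytest.approx(15.4, rel=1e-8)
        assert fit.x0 == pytest.approx(3.5, rel=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_zero_slope_degenerate(self):
        pts = [
            TrialPoint(float(af_from_lambda(l)), 12.0, n_cells=500)
            for l in np.linspace(0.3, 3.0, 8)
        ]
        fit = fit_universal_curve(pts)
        assert fit.k == pytest.approx(0.0, abs=1e-8)
        assert fit.x0 == pytest.approx(12.0, rel=1e-8)

    def test_identical_af_rejected(self):
        pts = [TrialPoint(0.5, 10.0 + i) for i in range(6)]
        with pytest.raises(ValueError, match="identical"):
            fit_universal_curve(pts)

    def test_minimum_trial_count(self):
        with pytest.raises(ValueError, match="5 trials"):
            fit_universal_curve(self.points_on_curve(10.0, 1.0, [0.5, 1.0, 2.0]))

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(3)
        lams = np.linspace(0.3, 4.0, 10)
        pts = [
            TrialPoint(float(af_from_lambda(l)), 15.0 * l + 2 + rng.normal(0, 1))
            for l in lams
        ]
        f1 = fit_universal_curve(pts)
        f2 = fit_universal_curve(list(reversed(pts)))
        assert f1.k == pytest.approx(f2.k, rel=1e-12)
        # duplicating one trial shifts the fit the same way regardless of order
        f3 = fit_universal_curve(pts + [pts[0]])
        f4 = fit_universal_curve([pts[0]] + pts)
        assert f3.k == pytest.approx(f4.k, rel=1e-12)

    def test_orthogonal_variant_agrees_on_clean_data(self):
        pts = self.points_on_curve(20.0, 5.0, np.linspace(0.3, 4.0, 10))
        ols = fit_universal_curve(pts, method="ols")
        odr = fit_universal_curve(pts, method="orthogonal")
        assert odr.k == pytest.approx(ols.k, rel=1e-3)
        assert odr.x0 == pytest.approx(ols.x0, rel=1e-2)

    def test_af_cap_flagged(self):
        pts = self.points_on_curve(10.0, 2.0, np.linspace(0.5, 3.0, 7))
        pts.append(TrialPoint(1.0, 40.0))
        fit = fit_universal_curve(pts)
        assert "af_capped" in fit.flags


class TestOffRate:
    def test_no_detachment_zero_rates(self):
        t = np.arange(0.0, 100.0, 0.5)
        curve = make_curve(t, np.ones_like(t), norm=500.0)
        force = ForceTrace(times_s=t, forces_pn=4.0 * t)
        series = off_rate_vs_force(curve, force)
        assert np.all(series.off_rate_per_s[np.isfinite(series.off_rate_per_s)] == 0.0)

    def test_misaligned_time_base_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        curve = make_curve(t, np.ones_like(t))
        short = ForceTrace(times_s=t[:100], forces_pn=4.0 * t[:100])
        with pytest.raises(ValueError, match="cover"):
            off_rate_vs_force(curve, short)

    def test_constant_hazard_recovered(self):
        # exponential decay at rate k under a ramp: every bin's estimate
        # should approximate k when bins are short
        t = np.arange(0.0, 50.0, 0.25)
        k = 0.02
        curve = make_curve(t, np.exp(-k * t), norm=10000.0)
        force = ForceTrace(times_s=t, forces_pn=4.0 * t)
        series = off_rate_vs_force(curve, force, bin_width_pn=8.0)
        ok = series.valid()
        assert np.all(np.abs(series.off_rate_per_s[ok] - k) / k < 0.05)

    def test_low_occupancy_bins_masked(self):
        t = np.arange(0.0, 100.0, 0.5)
        curve = make_curve(t, np.exp(-0.1 * t), norm=20.0)
        force = ForceTrace(times_s=t, forces_pn=4.0 * t)
        series = off_rate_vs_force(curve, force, bin_width_pn=20.0)
        assert np.any(~np.isfinite(series.off_rate_per_s))
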