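"""Detachment curves and adhesion frequency from frame counts."""

import numpy as np
import pytest

from cfmavidity import (
    BondModel,
    CountTrace,
    CurveOrigin,
    adhesion_frequency,
    average_curves,
    build_detachment_curve,
)
from cfmavidity.detachment import JITTER_EPSILON, flag_monolayer_qc
from cfmavidity.force import ForceTrace
from cfmavidity.simulate import batch_rupture_times


def make_trace(counts, dt=0.25, **kw):
    counts = np.asarray(counts, dtype=float)
    return CountTrace(times_s=dt * np.arange(len(counts)), target_counts=counts, **kw)


class TestCountTrace:
    def test_rejects_misaligned_or_negative(self):
        with pytest.raises(ValueError):
            CountTrace(times_s=np.array([0.0, 1.0]), target_counts=np.array([1.0]))
        with pytest.raises(ValueError):
            make_trace([-1, 2])
        with pytest.raises(ValueError):
            CountTrace(times_s=np.array([0.0, 0.0]), target_counts=np.array([1.0, 1.0]))

    def test_csv_round_trip(self, tmp_path):
        trace = make_trace([5, 5, 4, 4], dt=1.0, rpm=np.zeros(4))
        path = tmp_path / "trace.csv"
        trace.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = CountTrace.from_frame(pd.read_csv(path))
        np.testing.assert_allclose(back.target_counts, trace.target_counts)
        np.testing.assert_allclose(back.rpm, trace.rpm)


class TestAdhesionFrequency:
    def test_constant_counts_give_unity(self):
        trace = make_trace(np.full(600, 100.0))
        res = adhesion_frequency(trace, 0.0, 120.0)
        assert res.adhesion_frequency == 1.0

    def test_simple_ratio(self):
        counts = np.concatenate([np.full(100, 200.0), np.full(500, 160.0)])
        res = adhesion_frequency(make_trace(counts), 0.0, 120.0)
        assert res.adhesion_frequency == pytest.approx(0.80)

    def test_no_cells_at_start_rejected(self):
        trace = make_trace(np.zeros(600))
        with pytest.raises(ValueError, match="no cells"):
            adhesion_frequency(trace, 0.0, 120.0)

    def test_overlapping_windows_rejected(self):
        trace = make_trace(np.full(40, 10.0))
        with pytest.raises(ValueError, match="overlap"):
            adhesion_frequency(trace, 0.0, 3.0, window_s=2.0)

    def test_flip_must_precede_spin(self):
        trace = make_trace(np.full(600, 10.0))
        with pytest.raises(ValueError):
            adhesion_frequency(trace, 120.0, 0.0)


class TestBuildDetachmentCurve:
    def test_no_detachment_constant_one(self):
        curve = build_detachment_curve(make_trace(np.full(400, 80.0)), t_origin_s=10.0)
        assert np.all(curve.fraction_bound == 1.0)
        assert curve.times_s[0] == 0.0

    def test_starts_at_exactly_one(self, lam2_trial):
        curve = build_detachment_curve(lam2_trial.count_trace, t_origin_s=120.0)
        assert curve.fraction_bound[0] == 1.0

    def test_matches_single_bond_exponential_survival(self):
        # constant-force single-bond rupture is a pure exponential clock:
        # the normalized curve must track exp(-k*t) within sampling error
        rng = np.random.default_rng(7)
        n = 4000
        k = 0.05
        ft = ForceTrace(times_s=np.array([0.0, 200.0]), forces_pn=np.array([0.0, 0.0]))
        times = batch_rupture_times(
            np.ones(n, dtype=int), BondModel(k0=k, f_beta_pn=10.0), ft, rng
        )
        frames = np.arange(0.0, 100.0, 0.25)
        counts = (times[None, :] > frames[:, None]).sum(axis=1)
        curve = build_detachment_curve(
            CountTrace(times_s=frames, target_counts=counts.astype(float)),
            t_origin_s=0.0,
        )
        expected = np.exp(-k * curve.times_s)
        assert np.max(np.abs(curve.fraction_bound - expected)) < 4 * np.sqrt(0.25 / n) + 0.02

    def test_jitter_robustness(self):
        base = np.linspace(100.0, 20.0, 400)
        rng = np.random.default_rng(0)
        jitter = rng.choice([-1.0, 0.0, 1.0], size=400)
        c_clean = build_detachment_curve(make_trace(base), t_origin_s=0.0)
        c_noisy = build_detachment_curve(make_trace(base + jitter), t_origin_s=0.0)
        assert np.max(np.abs(c_clean.fraction_bound - c_noisy.fraction_bound)) < JITTER_EPSILON

    def test_zero_normalization_rejected(self):
        counts = np.concatenate([np.full(50, 10.0), np.zeros(50)])
        with pytest.raises(ValueError, match="zero cells"):
            build_detachment_curve(make_trace(counts), t_origin_s=20.0)

    def test_even_smoothing_window_rejected(self, lam2_trial):
        with pytest.raises(ValueError, match="odd"):
            build_detachment_curve(lam2_trial.count_trace, smoothing_window=4)

    def test_near_monotone_after_filtering(self, lam2_trial):
        curve = build_detachment_curve(lam2_trial.count_trace, t_origin_s=120.0)
        increases = np.diff(curve.fraction_bound)
        assert np.max(increases, initial=0.0) < JITTER_EPSILON

    def test_flip_origin_consistent_with_adhesion_frequency(self, lam2_trial):
        af = adhesion_frequency(lam2_trial.count_trace, 0.0, 120.0)
        curve = build_detachment_curve(
            lam2_trial.count_trace, origin=CurveOrigin.FLIP, t_origin_s=0.0
        )
        assert curve.value_at(119.0) == pytest.approx(af.adhesion_frequency, abs=0.02)


class TestAverageCurves:
    def make_constant(self, value, n=50):
        t = np.arange(n, dtype=float)
        from cfmavidity import DetachmentCurve

        return DetachmentCurve(t, np.full(n, value), 100.0, CurveOrigin.CENTRIFUGE_START)

    def test_identical_curves_zero_sd(self):
        c = self.make_constant(0.7)
        mean, sd = average_curves([c, c, c], np.arange(0.0, 40.0))
        np.testing.assert_allclose(mean, 0.7)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_two_constant_curves(self):
        mean, sd = average_curves(
            [self.make_constant(1.0), self.make_constant(0.0)], np.arange(0.0, 40.0)
        )
        np.testing.assert_allclose(mean, 0.5)
        np.testing.assert_allclose(sd, np.sqrt(0.5), rtol=1e-12)

    def test_requires_two_curves_and_overlap(self):
        c = self.make_constant(1.0)
        with pytest.raises(ValueError):
            average_curves([c], np.arange(10.0))
        with pytest.raises(ValueError):
            average_curves([c, c], np.arange(0.0, 100.0))

    def test_replicate_mean_tracks_generating_survival(self, cell, ramp_protocol):
        # 5 simulated replicates: the averaged curve should stay within a
        # few standard errors of the model's survival at most grid points
        from cfmavidity import simulate_trial

        curves = []
        for s in range(5):
            trial = simulate_trial(
                BondModel(lam=1.0), ramp_protocol, cell=cell, n_cells=500, seed=300 + s
            )
            curves.append(build_detachment_curve(trial.count_trace, t_origin_s=120.0))
        grid = np.arange(0.0, 200.0, 2.0)
        mean, sd = average_curves(curves, grid)
        stack = np.vstack([np.interp(grid, c.times_s, c.fraction_bound) for c in curves])
        within = np.abs(mean - stack.mean(axis=0)) <= 2 * sd / np.sqrt(5) + 1e-12
        assert within.mean() >= 0.95


class TestMonolayerQC:
    def test_flags_coverage_drop(self):
        mono = np.concatenate([np.full(100, 50.0), np.full(300, 30.0)])
        trace = make_trace(np.full(400, 10.0), monolayer_counts=mono)
        assert flag_monolayer_qc(trace)

    def test_stable_monolayer_not_flagged(self):
        trace = make_trace(np.full(400, 10.0), monolayer_counts=np.full(400, 50.0))
        assert not flag_monolayer_qc(trace)
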