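"""Generator correctness: determinism, ground-truth bookkeeping, moments."""

import logging

import numpy as np
import pytest
from scipy import stats

import trapcycle as tc


class TestTrapTraceGenerator:
    def test_same_seed_bit_identical(self):
        p = tc.TrapSimParams(seed=42, duration=2.0)
        t1, e1 = tc.simulate_unloaded_trace(p)
        t2, e2 = tc.simulate_unloaded_trace(p)
        np.testing.assert_array_equal(t1.motor_pos, t2.motor_pos)
        np.testing.assert_array_equal(t1.transducer_pos, t2.transducer_pos)
        assert [(a.start, a.stop) for a in e1] == [(b.start, b.stop) for b in e2]

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_ground_truth_events_inside_trace_and_disjoint(self, seed):
        p = tc.TrapSimParams(seed=seed, duration=10.0, attachment_rate=5.0,
                             detachment_rate=20.0)
        trace, truth = tc.simulate_unloaded_trace(p)
        for ev in truth:
            assert 0.0 <= ev.start < ev.stop <= trace.duration
            assert ev.start <= ev.substep2_time <= ev.stop
        for a, b in zip(truth.events, truth.events[1:]):
            assert a.stop <= b.start

    def test_zero_attachment_rate_gives_no_events(self):
        p = tc.TrapSimParams(seed=1, duration=3.0, attachment_rate=0.0)
        trace, truth = tc.simulate_unloaded_trace(p)
        assert len(truth) == 0
        # covariance stationary: windowed covariance mean matches the
        # free-state level rho * sd^2 throughout
        cov = tc.running_covariance(trace)
        expected = p.correlation_free * p.bead_noise_sd_free**2
        assert abs(np.mean(cov.values) - expected) < 0.1 * expected

    def test_trace_too_short_raises(self):
        p = tc.TrapSimParams(seed=1, duration=0.01)
        with pytest.raises(ValueError, match="trace too short"):
            tc.simulate_unloaded_trace(p)

    def test_invalid_correlation_ordering_rejected(self):
        p = tc.TrapSimParams(correlation_free=0.3, correlation_bound=0.5)
        with pytest.raises(ValueError, match="correlation"):
            p.validate()

    def test_mean_duration_matches_detachment_rate_at_saturating_atp(self):
        # with the substep-2 (ADP) stage fast, attachment durations are
        # exponential at the detachment rate: mean ~ 1/12.06 s within 3 SE
        durations = []
        for i in range(2):
            p = tc.TrapSimParams(seed=50 + i, duration=60.0, attachment_rate=20.0,
                                 detachment_rate=12.06, substep2_rate=2000.0)
            _, truth = tc.simulate_unloaded_trace(p)
            durations.extend(truth.durations)
        durations = np.asarray(durations)
        assert durations.size > 400
        se = durations.std() / np.sqrt(durations.size)
        assert abs(durations.mean() - 1 / 12.06) < 3 * se + 1 / 2000.0

    def test_duration_and_gap_moments_match_analytic(self):
        # sample statistics vs analytic moments of the generative model
        p = tc.TrapSimParams(seed=9, duration=120.0, attachment_rate=20.0,
                             detachment_rate=10.0, substep2_rate=60.0)
        _, truth = tc.simulate_unloaded_trace(p)
        d = truth.durations
        gaps = np.asarray(truth.gaps)
        assert d.size >= 500
        mean_d = 1 / 60.0 + 1 / 10.0
        assert abs(d.mean() - mean_d) < 4 * d.std() / np.sqrt(d.size)
        assert abs(gaps.mean() - 1 / 20.0) < 4 * gaps.std() / np.sqrt(gaps.size)


class TestIsometricEvents:
    def test_force_independent_limit_is_plain_exponential(self):
        p = tc.ForceEventSimParams(k0=10.0, d_bell=0.0, n_events=3000,
                                   dead_time=0.0, seed=3)
        ev = tc.simulate_isometric_events(p)
        # KS against Exp(10) on the lifetimes, ignoring forces
        stat = stats.kstest(ev[:, 1], "expon", args=(0, 1 / 10.0)).statistic
        assert stat < 1.36 / np.sqrt(ev.shape[0]) * 1.5

    def test_efold_slowing_at_force_kT_over_d(self):
        # F = kT/d gives mean lifetime e/k0, within 3 SE at n=5000
        p = tc.ForceEventSimParams(
            k0=32.9, d_bell=0.80, kT=4.05, force_mean=5.0625, force_sd=1e-6,
            force_bounds=(5.06, 5.065), n_events=5000, dead_time=0.0, seed=4,
        )
        ev = tc.simulate_isometric_events(p)
        se = ev[:, 1].std() / np.sqrt(ev.shape[0])
        assert abs(ev[:, 1].mean() - np.e / 32.9) < 3 * se

    def test_dead_time_censoring_keeps_only_long_lifetimes(self):
        p = tc.ForceEventSimParams(n_events=2500, dead_time=0.016, seed=5)
        ev = tc.simulate_isometric_events(p)
        assert ev.shape == (2500, 2)
        assert np.all(ev[:, 1] >= 0.016)

    def test_force_moments_match_truncated_normal_without_censoring(self):
        p = tc.ForceEventSimParams(n_events=2500, dead_time=0.0, seed=5)
        ev = tc.simulate_isometric_events(p)
        lo, hi = p.force_bounds
        a = (lo - p.force_mean) / p.force_sd
        b = (hi - p.force_mean) / p.force_sd
        mean_f = stats.truncnorm.mean(a, b, loc=p.force_mean, scale=p.force_sd)
        assert abs(ev[:, 0].mean() - mean_f) < 4 * ev[:, 0].std() / np.sqrt(2500)

    def test_invalid_kt_rejected(self):
        with pytest.raises(ValueError, match="kT"):
            tc.ForceEventSimParams(kT=0.0).validate()


class TestTransientGenerator:
    def test_noiseless_single_rate_recovered_exactly(self):
        p = tc.TransientSimParams(rates=(69.0,), noise_sd=0.0, duration=0.2,
                                  n_points=400, seed=0)
        tr = tc.simulate_transient(p)
        fit = tc.fit_exp_decay(tr, n_phases=1)
        assert fit.rates[0] == pytest.approx(69.0, rel=1e-6)

    def test_two_phase_fractional_amplitude_recovered(self):
        p = tc.TransientSimParams(
            kind="pi_release", rates=(15.8, 0.37), fractional_amplitudes=(0.27, 0.73),
            noise_sd=0.004, duration=21.0, split_timebase=(1000, 1000),
            split_durations=(1.0, 20.0), seed=8,
        )
        tr = tc.simulate_transient(p)
        fit = tc.fit_exp_decay(tr, n_phases=2)
        assert fit.fractional_amplitudes[0] == pytest.approx(0.27, abs=0.03)
        assert fit.rates[0] == pytest.approx(15.8, rel=0.1)

    def test_turnover_returns_blank_and_bleach_subtraction_recovers_rate(self):
        p = tc.TransientSimParams(
            kind="mant_turnover", rates=(0.0047,), bleach_fraction=0.10,
            bleach_rate=0.002, noise_sd=0.01, duration=1000.0, n_points=2000,
            seed=12,
        )
        sample, blank = tc.simulate_transient(p)
        fit = tc.fit_exp_decay(tc.correct_photobleach(sample, blank), n_phases=1)
        assert fit.rates[0] == pytest.approx(0.0047, rel=0.10)

    def test_poorly_sampled_decay_logs_warning(self, caplog):
        p = tc.TransientSimParams(rates=(0.1,), duration=1.0, n_points=50, seed=0)
        with caplog.at_level(logging.WARNING, logger="trapcycle.synthkin"):
            tc.simulate_transient(p)
        assert any("poorly sampled" in r.message for r in caplog.records)

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tc.TransientSimParams(rates=(1.0, 2.0),
                                  fractional_amplitudes=(0.5, 0.6)).validate()


class TestAtpaseGenerator:
    def test_half_saturation_slope_identity(self):
        vmax, km, heads = 2.0, 5.0, 0.1
        (curve,) = tc.simulate_atpase_progress(vmax, km, [km], heads, noise_sd=0.0)
        rate = tc.nadh_slope_to_rate(curve, heads=heads)
        assert rate == pytest.approx(vmax / 2, rel=1e-9)

    def test_noiseless_mm_refit_exact(self):
        concs = [1.0, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0]
        curves = tc.simulate_atpase_progress(2.35, 7.65, concs, heads=0.1, noise_sd=0.0)
        rates = [tc.nadh_slope_to_rate(c, heads=0.1) for c in curves]
        mm = tc.fit_michaelis_menten(concs, rates, n_boot=0)
        assert mm.vmax == pytest.approx(2.35, rel=1e-6)
        assert mm.km == pytest.approx(7.65, rel=1e-6)

    def test_slope_to_rate_arithmetic(self):
        t = np.linspace(0, 110, 111)
        tr = tc.Transient(time=t, signal=1.0 - 6.22e-4 * t, kind="nadh")
        assert tc.nadh_slope_to_rate(tr, heads=0.1) == pytest.approx(1.0, rel=1e-9)


class TestGlidingGenerator:
    def test_pure_species_endpoint_means(self):
        model = tc.MixtureModel(v_fast=1.6, v_slow=0.46, drag_weight=8.0)
        table = tc.simulate_gliding_velocities(
            [0.0, 1.0], model, n_per_fraction=200, noise_sd=0.05, seed=3
        )
        s = tc.summarize_gliding(table, weighted=False)
        assert s.loc[s.fraction_slow == 0.0, "mean_velocity_um_s"].iloc[0] == pytest.approx(1.6, abs=0.02)
        assert s.loc[s.fraction_slow == 1.0, "mean_velocity_um_s"].iloc[0] == pytest.approx(0.46, abs=0.02)

    def test_zero_noise_gives_model_velocity_exactly(self):
        model = tc.MixtureModel(drag_weight=4.0)
        table = tc.simulate_gliding_velocities([0.3], model, n_per_fraction=5,
                                               noise_sd=0.0, seed=0)
        v = tc.mixture_velocity(0.3, model)
        assert np.allclose(table["velocity_um_s"], v)

    def test_velocity_strictly_decreasing_in_slow_fraction(self):
        for w in (0.5, 2.0, 20.0):
            model = tc.MixtureModel(drag_weight=w)
            xs = np.linspace(0, 1, 41)
            v = tc.mixture_velocity(xs, model)
            assert np.all(np.diff(v) < 0)
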