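"""Substeps, ensemble averages, event forces and the Bell MLE."""

import numpy as np
import pytest

import trapcycle as tc
from trapcycle.datatypes import Event, TrapTrace


def _step_trace(s1=3.88, s2=0.94, start=0.5, stop=0.6, step2_at=0.55, fs=10_000.0,
                duration=1.0):
    """Noiseless two-substep event embedded in a flat trace."""
    n = int(duration * fs)
    pos = np.zeros(n)
    pos[int(start * fs) : int(stop * fs)] += s1
    pos[int(step2_at * fs) : int(stop * fs)] += s2
    return TrapTrace(motor_pos=pos.copy(), transducer_pos=pos, sampling_rate=fs)


class TestSubsteps:
    def test_noiseless_event_recovers_substeps_exactly(self):
        trace = _step_trace()
        ev = Event(start=0.5, stop=0.6)
        s1, s2, tot = tc.compute_substeps(trace, ev)
        assert (s1, s2, tot) == pytest.approx((3.88, 0.94, 4.82), abs=1e-12)

    def test_fast_substep2_folds_into_first_window(self):
        # step 2 before the post-attachment window: measured substep2 ~ 0
        # and the measured total equals the measured substep 1
        trace = _step_trace(step2_at=0.5005)
        s1, s2, tot = tc.compute_substeps(trace, Event(start=0.5, stop=0.6))
        assert s2 == pytest.approx(0.0, abs=1e-12)
        assert tot == pytest.approx(s1, abs=1e-12)

    def test_event_shorter_than_window_scheme_flagged_missing(self):
        trace = _step_trace(stop=0.506)
        s1, s2, tot = tc.compute_substeps(trace, Event(start=0.5, stop=0.506))
        assert np.isnan(s1) and np.isnan(s2) and np.isnan(tot)

    def test_mean_total_step_recovered_through_detection(self, wt_unloaded_dataset):
        totals = np.concatenate(
            [
                [e.total_step for e in detected if np.isfinite(e.total_step)]
                for _, _, detected in wt_unloaded_dataset
            ]
        )
        assert totals.size >= 150
        assert abs(totals.mean() - 4.82) < 0.5


class TestEnsembleAverage:
    def test_forward_rate_matches_adp_release(self, wt_event_pairs):
        ens = tc.ensemble_average(wt_event_pairs, direction="forward")
        assert 58.0 <= ens.fitted_rate <= 71.0
        # plateau minus pre-attachment baseline ~ total step within 2x SEM
        assert ens.plateau_level == pytest.approx(4.82, abs=0.5)
        assert ens.initial_level == pytest.approx(3.88, abs=0.5)

    def test_reverse_rate_matches_atp_detachment(self, wt_event_pairs):
        ens = tc.ensemble_average(wt_event_pairs, direction="reverse")
        assert ens.fitted_rate == pytest.approx(5.5, rel=0.25)

    def test_slow_adp_release_recovered(self):
        # M493I-like kinetics: substep 1 -> 2 transition at 11 /s
        pairs = []
        for i in range(15):
            p = tc.TrapSimParams(seed=5000 + i, duration=15.0, attachment_rate=2.0,
                                 detachment_rate=5.0, substep2_rate=11.0)
            trace, _ = tc.simulate_unloaded_trace(p)
            cov = tc.running_covariance(trace)
            try:
                thr = tc.fit_cov_double_gaussian(cov, seed=0)
            except tc.StatesNotSeparableError:
                continue
            pairs.extend((trace, e) for e in tc.detect_events(cov, thr))
        ens = tc.ensemble_average(pairs, direction="forward")
        assert 9.5 <= ens.fitted_rate <= 13.3

    def test_identical_noiseless_events_average_to_single_event(self):
        trace = _step_trace()
        pairs = [(trace, Event(start=0.5, stop=0.6))] * 12
        ens = tc.ensemble_average(pairs, direction="forward")
        single = trace.transducer_pos[5000:6000]
        np.testing.assert_allclose(ens.mean_position, single, atol=1e-12)
        assert ens.mean_position[-1] - ens.mean_position[0] == pytest.approx(0.94, abs=1e-12)

    def test_too_few_events_rejected(self):
        trace = _step_trace()
        with pytest.raises(ValueError, match="at least 10"):
            tc.ensemble_average([(trace, Event(0.5, 0.6))] * 5)


class TestEventForce:
    def _force_trace(self, level=5.0, baseline=0.0, fs=10_000.0):
        n = int(1.0 * fs)
        force = np.full(n, baseline)
        force[int(0.4 * fs) : int(0.6 * fs)] = level
        pos = np.zeros(n)
        return TrapTrace(motor_pos=pos.copy(), transducer_pos=pos, force=force,
                         sampling_rate=fs, mode="isometric")

    def test_constant_force_zero_baseline(self):
        trace = self._force_trace(5.0, 0.0)
        assert tc.event_mean_force(trace, Event(0.4, 0.6)) == pytest.approx(5.0)

    def test_baseline_subtraction(self):
        # 5 pN during the event on a 1 pN standing baseline -> 4 pN
        n = trace = self._force_trace(5.0, 1.0)
        trace.force[int(0.4 * trace.sampling_rate) : int(0.6 * trace.sampling_rate)] = 5.0
        assert tc.event_mean_force(trace, Event(0.4, 0.6)) == pytest.approx(4.0)

    def test_missing_force_channel_rejected(self):
        trace = _step_trace()
        trace.mode = "isometric"
        with pytest.raises(ValueError, match="force"):
            tc.event_mean_force(trace, Event(0.5, 0.6))

    def test_simulated_clamp_forces_recovered(self):
        p = tc.TrapSimParams(seed=31, duration=15.0, attachment_rate=2.0,
                             substep2_rate=1000.0)
        fp = tc.ForceEventSimParams(k0=20.0, d_bell=0.5)
        trace, truth = tc.simulate_isometric_trace(p, fp)
        errs = [
            tc.event_mean_force(trace, ev) - ev.mean_force
            for ev in truth
            if ev.duration > 0.02
        ]
        errs = np.array(errs)
        # per-event recovery within 5 sigma of the combined event-window and
        # 1 ms baseline-window noise (force channel SD 0.3 pN)
        n_base = int(0.001 * trace.sampling_rate)
        se = 0.3 * np.sqrt(1.0 / n_base)
        assert np.all(np.abs(errs) < 5 * se)


class TestBellFit:
    def test_parameters_recovered_within_printed_intervals(self):
        params = tc.ForceEventSimParams(k0=32.9, d_bell=0.80, kT=4.05,
                                        n_events=2000, seed=11)
        pairs = tc.simulate_isometric_events(params)
        fit = tc.fit_bell(pairs, kT=4.05, n_boot=0)
        assert 28.8 <= fit.k0 <= 35.3
        assert 0.62 <= fit.d_bell <= 0.97

    def test_zero_distance_truth_matches_closed_form_estimator(self):
        params = tc.ForceEventSimParams(k0=12.06, d_bell=0.0, n_events=2000,
                                        dead_time=0.016, seed=3)
        pairs = tc.simulate_isometric_events(params)
        fit = tc.fit_bell(pairs, n_boot=0)
        closed = 1.0 / (pairs[:, 1].mean() - 0.016)
        assert fit.k0 == pytest.approx(closed, rel=0.01)

    def test_d_fixed_at_zero_equals_truncated_exponential_mle(self):
        params = tc.ForceEventSimParams(k0=20.0, d_bell=0.4, n_events=500,
                                        dead_time=0.016, seed=9)
        pairs = tc.simulate_isometric_events(params)
        fit = tc.fit_bell(pairs, n_boot=0, fix_d=0.0)
        closed = 1.0 / (pairs[:, 1].mean() - 0.016)
        assert fit.k0 == pytest.approx(closed, rel=1e-6)

    def test_identical_forces_not_identifiable(self):
        rng = np.random.default_rng(0)
        pairs = np.column_stack([np.full(100, 4.0), 0.02 + rng.exponential(0.1, 100)])
        with pytest.raises(tc.NonIdentifiableError):
            tc.fit_bell(pairs, n_boot=0)

    def test_high_force_exclusion_does_not_inflate_k0(self):
        # on Bell-generated data, dropping >10 pN events must not push the
        # fitted k0 up beyond sampling noise (one-sided, 3 SE)
        params = tc.ForceEventSimParams(k0=30.0, d_bell=0.6, n_events=2000,
                                        force_bounds=(0.2, 14.0), seed=13)
        pairs = tc.simulate_isometric_events(params)
        fit_all = tc.fit_bell(pairs, exclude_above=np.inf, n_boot=0)
        fit_ex = tc.fit_bell(pairs, exclude_above=10.0, n_boot=0)
        se = 3 * 30.0 / np.sqrt(fit_ex.n_events)
        assert fit_ex.k0 <= fit_all.k0 + se

    def test_bootstrap_determinism_and_boundary_reporting(self):
        params = tc.ForceEventSimParams(k0=15.0, d_bell=0.05, n_events=300, seed=21)
        pairs = tc.simulate_isometric_events(params)
        f1 = tc.fit_bell(pairs, n_boot=60, seed=5)
        f2 = tc.fit_bell(pairs, n_boot=60, seed=5)
        assert f1.k0_ci == f2.k0_ci and f1.d_ci == f2.d_ci
        # d near the 0 boundary: CI lower bound collapses to 0
        assert f1.d_ci[0] >= 0.0

    def test_bootstrap_ci_covers_true_k0(self):
        # 95% CI coverage over independent replicates (binomial tolerance)
        hits = 0
        n_rep = 50
        for r in range(n_rep):
            params = tc.ForceEventSimParams(k0=25.0, d_bell=0.7, n_events=300,
                                            seed=6000 + r)
            pairs = tc.simulate_isometric_events(params)
            fit = tc.fit_bell(pairs, n_boot=150, seed=r)
            if fit.k0_ci[0] <= 25.0 <= fit.k0_ci[1]:
                hits += 1
        assert hits >= 43


class TestBinning:
    def test_bin_counts_and_partial_bin_rule(self):
        rng = np.random.default_rng(1)
        pairs = np.column_stack([rng.uniform(1, 8, 60), rng.exponential(0.1, 60)])
        assert len(tc.bin_detachment_vs_force(pairs[:50], 25)) == 2
        assert len(tc.bin_detachment_vs_force(pairs, 25)) == 2

    def test_binned_rates_decrease_with_force_on_bell_truth(self):
        forces = np.linspace(0.5, 9.5, 500)
        lifetimes = 1.0 / tc.bell_rate(forces, 30.0, 0.8)  # conditional means
        binned = tc.bin_detachment_vs_force(np.column_stack([forces, lifetimes]))
        assert np.all(np.diff(binned["rate_per_s"]) < 0)
        assert np.all(np.diff(binned["mean_force_pN"]) > 0)
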