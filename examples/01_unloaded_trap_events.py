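"""Detect single actomyosin attachments in a simulated unloaded trap record.

Simulates a 1 µM-ATP-like two-bead recording (ADP release 62 /s, ATP-induced
detachment 5.5 /s), detects events from the inter-bead covariance drop, and
reports the dwell-time MLE plus the two-substep working stroke.
"""

import numpy as np

import trapcycle as tc

pairs, durations = [], []
for i in range(6):
    params = tc.TrapSimParams(seed=100 + i, duration=15.0, attachment_rate=2.0,
                              detachment_rate=5.5, substep2_rate=62.0,
                              substep1=3.88, substep2=0.94)
    trace, truth = tc.simulate_unloaded_trace(params)
    cov = tc.running_covariance(trace, window=0.008)
    thr = tc.fit_cov_double_gaussian(cov, seed=0)
    events = tc.detect_events(cov, thr, dead_time=0.016)
    tc.annotate_substeps(trace, events)
    durations.extend(events.durations)
    pairs.extend((trace, ev) for ev in events)
    if i == 0:
        print(f"trace 0: covariance peaks {thr.mu_high:.1f} / {thr.mu_low:.2f} nm^2, "
              f"{len(events)} events ({len(truth)} simulated)")

fit = tc.fit_exponential_mle(durations, dead_time=0.016, n_boot=500, seed=1)
totals = np.array([ev.total_step for _, ev in pairs])
totals = totals[np.isfinite(totals)]
fwd = tc.ensemble_average(pairs, direction="forward")

print(f"{len(pairs)} events pooled over 6 recordings")
print(f"k_detach = {fit.rates[0]:.2f} /s (95% CI {fit.rate_cis[0][0]:.2f}-"
      f"{fit.rate_cis[0][1]:.2f}); at 1 uM ATP this is set by ATP binding")
print(f"mean total step = {totals.mean():.2f} nm (generative 4.82)")
print(f"forward-ensemble rise = {fwd.fitted_rate:.1f} /s "
      f"-> the substep 1 -> 2 transition, i.e. ADP release (generative 62)")
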