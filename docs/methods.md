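# Methods

`trapcycle` implements the quantitative workflow used to characterize a
β-cardiac myosin construct from three-bead optical-trap recordings and
ensemble kinetics, together with seeded generators that produce synthetic
data with exact ground truth for every stage. This note records the models,
the defaults and why they were chosen, the numerical choices, and what the
synthetic data do and do not establish about real recordings.

## Trapped-bead model and event detection

**Generative model.** Each bead position is a discrete-time AR(1)
(Ornstein–Uhlenbeck) process with stationary SD `bead_noise_sd_*` and
relaxation rate `relaxation_rate` (1/s); a shared innovation component sets
the inter-bead correlation. Actomyosin attachment stiffens the dumbbell,
modeled as a drop in both the per-bead SD (7 → 2 nm default) and the
inter-bead correlation (0.9 → 0.2), so the windowed covariance falls from
~44 nm² to ~0.8 nm² during attachments. Only this second-moment structure
matters for covariance-drop detection, so no hydrodynamic coupling or
filament compliance is simulated. The stationary free-bead SD of 7 nm is
`sqrt(kT/k)` for a 0.08 pN/nm trap at 20 °C (kT = 4.05 pN·nm, the package
default throughout). Real covariance magnitudes are not published for this
assay; the defaults are chosen to give a detection contrast comparable to
published example traces and are fully configurable.

**Attachment kinetics are sequential.** On binding, substep 1 (3.88 nm
default) appears immediately (coupled to phosphate release); substep 2
(0.94 nm) follows after an exponential wait at `substep2_rate` (ADP
release); detachment follows substep 2 after an exponential wait at
`detachment_rate` (ATP binding to the rigor head). This ordering — rather
than an independent substep-2 clock racing a detachment clock — is the
actomyosin cycle's own causal chain, and it is what makes the time-forward
ensemble average rise at exactly the ADP-release rate and the time-reversed
average at exactly the ATP-binding rate (an independent clock would make
the forward rise report the *sum* of the two rates). At saturating ATP, set
`substep2_rate` large so attachment durations are exponential at
`detachment_rate`, or `detachment_rate` large so durations report ADP
release.

**Sampling.** Default 10 kHz was considered but rejected: window sizes are
specified in seconds so detection is rate-independent, but at 10 kHz each
sample carries enough leverage on the 8 ms windowed covariance that the
detected boundary *conditions on* a noise excursion located exactly in the
pre-attachment substep window, biasing the extracted total step by ~+0.7 nm.
The default is 25 kHz with `relaxation_rate` 25,000 1/s (the physical
corner frequency of a 750 nm bead in a 0.08 pN/nm trap is ~12,700 1/s),
which reduces the conditioning bias to ~+0.2 nm while keeping a 15 s trace
at 375k samples — well under a second to simulate and detect. The substep
acceptance pipeline uses 50 kHz for additional margin. (Real instruments
acquire at 250 kHz, where the effect is negligible.)

**Detection.** The running covariance is computed exactly over a trailing
8 ms window (cumulative sums, O(n)); its histogram is fit by a two-component
Gaussian mixture (EM, k-means init, three seeded restarts), components
labeled by mean. A trace is declared single-state ("states not separable")
when a one-component fit has the better BIC or the component means are
closer than twice the narrower SD or half the wider SD — the BIC clause is
needed because EM happily splits a unimodal histogram into two overlapping
components. Events use the hysteresis trigger: open below the high
(detached) peak, confirm below the low (attached) peak, close above the
high peak; events shorter than the 16 ms instrument dead time and partial
events at trace edges are discarded.

**Boundary placement.** The confirm/close crossings sit at the *centers* of
the attached/detached covariance distributions, so their latency relative to
the true transition is heavy-tailed (the covariance hovers around each
threshold between transitions); measured on ground truth, 20–30% of such
boundaries land >4 ms off at desk-scale window SNR, which throws the
fixed-offset substep windows outside the event. Reported boundaries are
therefore refined to the midpoint-threshold crossing of the covariance
*ramp* (last down-crossing before confirmation, last up-crossing before
closure) plus half a window — a steep-ramp crossing with millisecond jitter
and no tail. `refine=False` restores the literal confirm/close convention.

## Substeps, ensembles, forces, Bell fit

Substeps average 1 ms of the transducer-bead position at three anchors:
ending 4 ms before attachment, starting 2 ms after attachment, ending 4 ms
before detachment (events shorter than 8 ms are flagged missing but still
count toward duration statistics). Ensemble averages align events at start
(forward) or stop (reverse), pad shorter events with the mean of 4 ms of
their own in-event data ending 1 ms before the terminal transition,
subtract each event's own 4 ms pre/post baseline, weight events equally,
and fit `offset + A(1 − exp(−kt))` by least squares with the rate bounded
away from zero (excluding the degenerate ramp solution); which bead is
averaged is configurable (transducer default).

Isometric event forces average the motor-bead force channel from 2 ms after
attachment to 2 ms before detachment, minus a 1 ms baseline centered 4 ms
after detachment. The Bell fit is an unbinned MLE: each lifetime is a
dead-time-truncated exponential at `k0·exp(−F·d/kT)`, optimized over
`(log k0, d)` with `d ≥ 0` (L-BFGS-B, three `d` starts), events above
10 pN excluded first (possible second-head interactions outside the clamp's
subsaturating range). CIs are 95% percentile intervals over seeded
event-level bootstrap resamples; a fit pinned at `d = 0` reports a CI lower
bound of zero; a design with all forces equal raises a non-identifiability
error. The same 16 ms dead time is used for isometric lifetimes as for
unloaded detection; the clamp's ~10 ms response is not separately modeled.
25-event force binning is provided for display only and is never fit.

## Dwell-time MLEs

The likelihood is the truncated-renormalized exponential (mixture), so the
single-phase MLE is the closed form `k = 1/(mean(t) − t0)` (the numerical
optimum is asserted against it in the tests). The two-phase MLE optimizes
`(log k1, log k2, logit a)` by Nelder–Mead with 10 seeded restarts, keeps
the best likelihood, orders components slow → fast, and warns when the
rates are within 2× of each other or one amplitude collapses below 1%.
Reattachment gap times are fit with `dead_time = 0`: gaps are delimited by
detection of the flanking events, not by the minimum-duration exclusion.
No upper measurement-window truncation is applied (recordings are long
relative to dwells). Bootstrap CIs resample dwells and are
seed-deterministic.

## Transients, ATPase, binding

Decay fits are nonlinear least squares of `offset + Σ Aᵢ exp(−kᵢ t)` with a
ladder of starting points; a signal span below 3× the first-difference
noise estimate is unidentifiable and raises. Split time bases are fit in
continuous time, never resampled. Photobleach blanks are subtracted
unscaled, matching the measured-blank procedure (the blank is interpolated
onto the sample time base if needed). NADH slopes convert to per-head rates
with ε = 6220 M⁻¹cm⁻¹ and a 1 cm path. Michaelis–Menten fits use bounded
least squares with three Km starts (best SSE kept): Km beyond 50× the
largest concentration raises "Km unbounded", Km at the zero boundary is
flagged. The second-order ATP-binding constant is the least-squares slope
of kobs vs [ATP] restricted to the low-substrate range, with a t-based CI.
Transient bootstraps resample residuals (fixed time design); MM and line
fits resample points. An optional ≥5 SD replicate-exclusion rule for
turnover replicates exists but is off by default and logged when applied.

## Cycle arithmetic

The SRX/DRX relation is implemented exactly as printed, `K_EQ = k_obs /
k_DRX`, with DRX head fraction `K/(1+K)` — this is the only reading that
reproduces the published constants (0.32 WT, 0.53 mutant) and fractions
(~25%, ~35%); the interconversion rates are individually unidentifiable
and are never estimated. Note the paper-internal spread: the WT text value
K = 0.33 gives 24.8% ≈ 25%, while the tabulated rates give K = 0.32 →
24.4%. Duty ratio is `DR = Vmax/k_ADP` (1/Vmax as whole-population cycle
time, 1/k_ADP as the strong-binding AM·ADP dwell); the S1 value divides by
the DRX fraction (S1 cannot form the folded-back state). Force-dependent
power is `P(F) = F·d_step·k_ADP(F)` with `k_ADP(F)` from the Bell fit; the
duty-ratio-corrected curve multiplies by `DR(F) = Vmax/k_ADP(F)`, so the
Bell factor cancels and the corrected power is exactly `F·d_step·Vmax` —
linear in force, with a mutant/WT ratio of `(4.68·2.35)/(4.82·1.20) = 1.90`
constant over 0–10 pN. The two distance symbols — the Bell distance
parameter `d_bell` and the working-stroke displacement `step_size` — are
separate fields and never interchanged.

## Mixed-motor gliding

The published quadratic's parameterization is not printed; the implemented
force balance gives the slow species an attachment flux proportional to v
(its on-time per encounter scales as 1/v) and weight `w`:

    (1 − x)(1 − v/v_fast) + x·w·(v/v_slow)(1 − v/v_slow) = 0,

a quadratic in v whose root in `[v_slow, v_fast]` is unique for x ∈ (0,1).
Endpoints are exact (`v(0) = v_fast`, `v(1) = v_slow`), v(x) is continuous
and non-increasing for any `w ≥ 0`, and large `w` reproduces the concave
"half the speed lost by 10% slow motors" shape. `w` is the single fitted
shape parameter (over log w; endpoints optionally co-fit). Velocity tables
are summarized per mole fraction by a trajectory-length-weighted Gaussian
mean and SD (unweighted switchable), the standard reduction of
tracked-filament data.

## Reproducibility and problem sizes

Every generator takes an integer seed and is bit-reproducible; the pipeline
derives per-stage substreams by hashing the stage name with the global
seed, so adding a stage never perturbs earlier stages' randomness. Result
JSONs embed the resolved config and package version and are byte-identical
across runs. Tests and the acceptance script use desk-scale sizes chosen so
sampling error is small against each published interval: 2,000 events for
dwell and Bell recoveries, ~500 detected events (≈30 recordings of 15 s)
for the substep pipeline, 2,000 points per transient, 8-concentration
titrations, 2,000 gap times for the reattachment mixture.

## What passing tests do and do not show

The generators emulate the *statistical structure* the analyses key on:
covariance drop with exponential kinetics, truncated-normal clamp forces
with Bell lifetimes, multi-exponential decays with an additive ~10%
photobleach, linear NADH progress curves, Gaussian-dispersed gliding
velocities. They omit instrument drift, trap-stiffness miscalibration,
filament compliance and series elasticity, the clamp's finite response
time, multi-molecule and second-head interactions, mixing artifacts in the
stopped flow, and tracking errors in motility movies. Parameter-recovery
tests therefore validate the estimators and their dead-time/bootstrap
machinery under the stated model, not robustness to those instrumental
effects. Known limitations: the covariance detector's boundary estimate
retains a small (~0.2 nm at 25 kHz) detection-conditioned bias in extracted
substeps at desk-scale sampling; the double-Gaussian separability test is
conservative on traces with very few events; and the mixture gliding model
is one defensible parameterization of an under-specified published model.
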